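"""Size-corrected assembly yields from agarose-gel band densitometry.

Intercalating-dye band intensity is proportional to total DNA mass, and all
assembly states here are built from identical scaffold tiles, so the molar
(per-particle) abundance of a band is its intensity divided by the number of
tiles in the structure.  Yields are the molar shares, directly comparable to
the nanopore-derived :class:`~origamipore.ecs.YieldReport` values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ecs import YieldReport


@dataclass(frozen=True)
class GelLaneTable:
    """Band intensities for one gel lane.

    ``bands`` is a tuple of ``(component_label, intensity, n_monomers)``
    with intensities in arbitrary densitometry units.
    """

    lane_label: str
    bands: tuple[tuple[str, float, int], ...]

    def __init__(self, lane_label, bands) -> None:
        bands = tuple((str(lab), float(inten), int(n)) for lab, inten, n in bands)
        if not bands:
            raise ValueError("lane needs at least one band")
        if any(inten < 0 for _, inten, _ in bands):
            raise ValueError("intensities must be non-negative")
        if any(n < 1 for _, _, n in bands):
            raise ValueError("n_monomers must be >= 1")
        object.__setattr__(self, "lane_label", str(lane_label))
        object.__setattr__(self, "bands", bands)


def gel_yields(lane: GelLaneTable, target_label: str | None = None) -> YieldReport:
    """Molar yields from one lane: ``intensity / n_monomers``, normalised.

    ``target_label`` defaults to the band of the largest structure (the
    intended end product of the assembly).
    """
    molar = [(lab, inten / n) for lab, inten, n in lane.bands]
    total = sum(m for _, m in molar)
    if total == 0:
        raise ValueError("all band intensities are zero; yields undefined")
    per_component = [(lab, 100.0 * m / total) for lab, m in molar]
    if target_label is None:
        target_label = max(lane.bands, key=lambda b: b[2])[0]
    labels = [lab for lab, _, _ in lane.bands]
    if target_label not in labels:
        raise KeyError(f"no band labelled {target_label!r} in lane {lane.lane_label!r}")
    return YieldReport(
        sample_label=lane.lane_label,
        per_component=per_component,
        target_label=target_label,
        target_yield=dict(per_component)[target_label],
    )


def compare_reports(nanopore, gel, margin: float = 5.0) -> pd.DataFrame:
    """Side-by-side nanopore vs gel yields, flagging large disagreements.

    Returns one row per (sample, component) with the two percentages, their
    difference (nanopore - gel) and a ``flagged`` column marking components
    where the methods differ by more than ``margin`` percentage points.

    Raises
    ------
    ValueError
        If the two report lists do not cover the same sample labels.
    """
    nano = {r.sample_label: r for r in nanopore}
    gels = {r.sample_label: r for r in gel}
    unmatched = sorted(set(nano) ^ set(gels))
    if unmatched:
        raise ValueError(f"sample labels not present in both report sets: {unmatched}")

    rows = []
    for label in nano:
        n_pc = dict(nano[label].per_component)
        g_pc = dict(gels[label].per_component)
        for comp in sorted(set(n_pc) | set(g_pc)):
            npct = n_pc.get(comp, 0.0)
            gpct = g_pc.get(comp, 0.0)
            diff = npct - gpct
            rows.append(
                {
                    "sample_label": label,
                    "component": comp,
                    "nanopore_percent": npct,
                    "gel_percent": gpct,
                    "difference": diff,
                    "flagged": abs(diff) > margin,
                }
            )
    return pd.DataFrame(rows)
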