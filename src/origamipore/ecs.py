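"""Equivalent-charge-surplus (ECS) deconvolution and assembly-yield analysis.

The ECS of a translocation event — the area of its conductive peak, pA*ms —
is conserved for a given assembly state and scales linearly with the number
of origami tiles, which makes the per-sample ECS histogram a superposition
of one Gaussian component per assembly state.  The deconvolution strategy is
*sequential anchoring*: the monomer sample is fitted with a single Gaussian;
each more complex sample is then fitted with one additional component while
the means identified in the simpler samples are held fixed.  Assembly yields
are the relative areas of the fitted components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .detect import EventTable

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class ECSComponent:
    """One Gaussian component of an ECS distribution.

    ``amplitude`` is on the histogram-count scale, so the component area is
    ``amplitude * sd * sqrt(2*pi)``; ``fixed_mean`` records whether the mean
    was anchored rather than fitted.
    """

    label: str
    mean: float
    sd: float
    amplitude: float
    fixed_mean: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def area(self) -> float:
        return self.amplitude * self.sd * _SQRT2PI


@dataclass
class ECSFitResult:
    """Multi-component Gaussian fit of one sample's ECS histogram."""

    components: list[ECSComponent]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    residual_ss: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        means = [c.mean for c in self.components]
        if not 1 <= len(means):
            raise ValueError("need at least one component")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("component means must be strictly increasing")

    def component(self, label: str) -> ECSComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component labelled {label!r}")

    def model(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted sum of Gaussians on ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.amplitude * np.exp(-0.5 * ((x - c.mean) / c.sd) ** 2)
        return out


@dataclass
class YieldReport:
    """Per-component assembly-yield percentages for one sample."""

    sample_label: str
    per_component: list[tuple[str, float]]
    target_label: str
    target_yield: float

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.per_component)
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"component percentages must sum to 100 (got {total})")
        if any(p < 0 for _, p in self.per_component):
            raise ValueError("percentages must be non-negative")

    def percent(self, label: str) -> float:
        for lab, p in self.per_component:
            if lab == label:
                return p
        raise KeyError(f"no component labelled {label!r}")


@dataclass(frozen=True)
class LinearECSModel:
    """OLS fit of mean ECS against assembly size (number of tiles)."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, n_monomers) -> np.ndarray:
        return self.slope * np.asarray(n_monomers, dtype=float) + self.intercept


def fit_ecs_distribution(
    ecs_values,
    n_components: int,
    anchors=(),
    bins="fd",
    anchor_slack: float = 0.0,
    backend: str = "histogram",
    sample_label: str = "",
) -> ECSFitResult:
    """Fit the ECS histogram with a sum of Gaussians, optionally anchored.

    Parameters
    ----------
    ecs_values
        Per-event ECS values (pA*ms); at least 100.
    n_components
        Number of Gaussian components (1-4 by convention; up to 8 allowed).
    anchors
        ``(component_index, mean)`` pairs whose means are held fixed
        (bit-exactly when ``anchor_slack`` is 0, the default; a small slack
        such as 0.05 lets anchored means move +/-5% to absorb pore-to-pore
        variability).
    bins
        Histogram binning (any ``numpy.histogram`` spec; Freedman-Diaconis
        by default).
    backend
        ``"histogram"`` (bounded least squares on bin counts, the default)
        or ``"em"`` (expectation-maximisation on the raw values with fixed
        anchored means, as a cross-check; results are mapped back to the
        histogram amplitude scale).

    Returns
    -------
    ECSFitResult
        Components sorted by mean and labelled I, II, ... in that order.
        ``n_components`` is an upper bound: when a free component converges
        onto an existing peak (mean separation below one sd, an
        unidentifiable split of a single peak), the fit is retried with one
        fewer component, so pure single-species samples come back with a
        single component even when more are allowed.
    """
    x = np.asarray(ecs_values, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 ECS values")
    if not 1 <= n_components <= 8:
        raise ValueError("n_components must be between 1 and 8")
    if np.unique(x).size < 3 * n_components:
        raise ValueError("fewer distinct ECS values than 3 x n_components")
    anchors = sorted((int(i), float(m)) for i, m in anchors)
    for i, m in anchors:
        if not 0 <= i < n_components:
            raise ValueError(f"anchor index {i} outside 0..{n_components - 1}")
        if not x.min() <= m <= x.max():
            raise ValueError(f"anchor mean {m} outside the data range")

    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_anchors = len(anchors)
    while True:
        if backend == "em":
            comps = _fit_em(x, n_components, dict(anchors), counts, edges)
        elif backend == "histogram":
            comps = _fit_histogram(
                x, n_components, dict(anchors), counts, centers, edges, anchor_slack
            )
        else:
            raise ValueError("backend must be 'histogram' or 'em'")
        # Degeneracy guard: a free component collapsing onto an existing
        # peak (mean separation below 0.6 sd) or a sub-bin spike inside a
        # neighbour's support is not a separately identifiable assembly
        # state, so the fit is retried with one fewer component.  Anchored
        # means are never the ones dropped.
        if n_components <= max(1, n_anchors) or _resolvable(comps, float(edges[1] - edges[0])):
            break
        n_components -= 1

    comps = sorted(comps, key=lambda c: c.mean)
    comps = [replace(c, label=ROMAN[i]) for i, c in enumerate(comps)]
    resid = counts - sum(
        c.amplitude * np.exp(-0.5 * ((centers - c.mean) / c.sd) ** 2) for c in comps
    )
    return ECSFitResult(
        components=comps,
        bin_edges=edges,
        bin_counts=counts,
        residual_ss=float(np.sum(resid**2)),
        sample_label=sample_label,
    )


def _resolvable(comps, bin_width: float) -> bool:
    """True when every *free* component is a distinguishable peak.

    Anchored components are externally attested assembly states and are
    never treated as spurious.  A free component is spurious when it
    collapses onto a neighbouring mean (separation within 0.6 of the free
    component's own sd — an unidentifiable split of one peak) or when it is
    a sub-bin spike inside another component's 2-sd support (a fit to
    histogram count noise rather than to an assembly state).
    """
    ordered = sorted(comps, key=lambda c: c.mean)
    for a, b in zip(ordered, ordered[1:]):
        free_sds = [c.sd for c in (a, b) if not c.fixed_mean]
        if free_sds and b.mean - a.mean <= 0.6 * max(free_sds):
            return False
    for c in ordered:
        if c.fixed_mean:
            continue
        if c.sd < bin_width and any(
            o is not c and abs(c.mean - o.mean) < 2.0 * o.sd for o in ordered
        ):
            return False
    return True


def _initial_free_means(x, n_free, anchor_means):
    """Free-mean starting points: quantile spacing over the data, restricted
    to values above the largest anchor when anchors are present (the free
    components describe the not-yet-identified, larger assemblies)."""
    if anchor_means:
        hi = x[x > max(anchor_means)]
        pool = hi if hi.size >= 10 else x
    else:
        pool = x
    qs = (np.arange(n_free) + 0.5) / n_free
    return np.quantile(pool, qs)


def _fit_histogram(x, n_components, anchors, counts, centers, edges, anchor_slack):
    rng_lo, rng_hi = float(x.min()), float(x.max())
    span = rng_hi - rng_lo
    bin_width = float(edges[1] - edges[0])
    anchor_means = [m for m in anchors.values()]
    free_idx = [i for i in range(n_components) if i not in anchors]
    init_free = _initial_free_means(x, len(free_idx), anchor_means)

    means0 = np.empty(n_components)
    for i, m in anchors.items():
        means0[i] = m
    for j, i in enumerate(free_idx):
        means0[i] = init_free[j]
    order_hint = np.argsort(means0)

    # sd inits from the spacing of the mean inits (half the distance to the
    # nearest neighbouring component); a single component starts at the
    # sample sd.  This encodes the anchoring structure: each component is
    # expected to describe the mass around its own mean, not a pedestal.
    sd_lo = 0.5 * bin_width  # precludes sub-bin spike components
    sd0 = np.empty(n_components)
    if n_components == 1:
        sd0[:] = x.std()
    else:
        rank_of = {i: r for r, i in enumerate(order_hint)}
        sorted_means = means0[order_hint]
        gaps = np.diff(sorted_means)
        for i in range(n_components):
            r = rank_of[i]
            near = [g for g in (gaps[r - 1] if r > 0 else None,
                                gaps[r] if r < gaps.size else None) if g is not None]
            sd0[i] = 0.5 * min(near) if near else max(span / 4.0, bin_width)

    # A component models one assembly state whose ECS spread (noise +
    # orientation variability) is empirically ~20% of its mean; an sd above
    # half the mean would be a background pedestal, not a state, and the
    # histogram LS objective otherwise genuinely prefers such pedestals on
    # heavily overlapping mixtures.  Anchored components are capped at half
    # their anchor; free components at half the data maximum.
    sd_hi = np.array(
        [
            max(0.5 * (anchors[i] if i in anchors else rng_hi), 2.0 * sd_lo)
            for i in range(n_components)
        ]
    )
    sd0 = np.clip(sd0, sd_lo, sd_hi)

    # amplitude inits by non-negative least squares given the init shapes
    # (raw local bin counts over-count shared mass in overlap regions and
    # push the optimiser toward zeroing a component)
    basis = np.exp(-0.5 * ((centers[:, None] - means0[None, :]) / sd0[None, :]) ** 2)
    amp0, _ = optimize.nnls(basis, counts.astype(float))
    amp0 = np.maximum(amp0, 1.0)

    # parameter vector: [free or slack-bounded means...] + [sds...] + [amps...]
    slack_means = anchor_slack > 0
    mean_param_idx = list(range(n_components)) if slack_means else free_idx
    # free components in an anchored fit describe larger, not-yet-identified
    # assemblies, so their means live above the largest anchor
    free_mean_lo = max(anchor_means) if anchor_means else rng_lo

    def unpack(p):
        k = len(mean_param_idx)
        means = means0.copy()
        means[mean_param_idx] = p[:k]
        sds = p[k : k + n_components]
        amps = p[k + n_components :]
        return means, sds, amps

    def residual(p):
        means, sds, amps = unpack(p)
        model = np.zeros_like(centers)
        for mu, sd, a in zip(means, sds, amps):
            model += a * np.exp(-0.5 * ((centers - mu) / sd) ** 2)
        return model - counts

    p0 = np.concatenate([means0[mean_param_idx], sd0, amp0])
    lo_means = [
        means0[i] * (1 - anchor_slack) if (slack_means and i in anchors) else free_mean_lo
        for i in mean_param_idx
    ]
    hi_means = [
        means0[i] * (1 + anchor_slack) if (slack_means and i in anchors) else rng_hi
        for i in mean_param_idx
    ]
    lower = np.concatenate([lo_means, np.full(n_components, sd_lo), np.zeros(n_components)])
    upper = np.concatenate([hi_means, sd_hi, np.full(n_components, np.inf)])
    p0 = np.clip(p0, lower, upper)

    res = optimize.least_squares(residual, p0, bounds=(lower, upper), max_nfev=20_000)
    if not res.success:
        raise RuntimeError(
            f"ECS histogram fit did not converge (status {res.status}); "
            f"initial means {means0.tolist()}, sd {sd0}, amplitudes {amp0.tolist()}"
        )
    means, sds, amps = unpack(res.x)
    fixed = [i in anchors and not slack_means for i in range(n_components)]
    # keep anchored means bit-exact
    for i, m in anchors.items():
        if not slack_means:
            means[i] = m
    return [
        ECSComponent(ROMAN[order_hint.tolist().index(i)], float(means[i]), float(sds[i]),
                     float(amps[i]), fixed[i])
        for i in range(n_components)
    ]


def _fit_em(x, n_components, anchors, counts, edges, n_iter=500, tol=1e-8):
    """EM on the raw ECS values with anchored means held fixed.

    Mixture weights map to histogram amplitudes via
    ``amplitude = weight * N * bin_width / (sd * sqrt(2*pi))`` so component
    areas stay proportional to weights.
    """
    n = x.size
    bin_width = float(edges[1] - edges[0])
    anchor_means = [m for m in anchors.values()]
    free_idx = [i for i in range(n_components) if i not in anchors]
    means = np.empty(n_components)
    for i, m in anchors.items():
        means[i] = m
    init_free = _initial_free_means(x, len(free_idx), anchor_means)
    for j, i in enumerate(free_idx):
        means[i] = init_free[j]
    cell = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
    sds = np.empty(n_components)
    weights = np.empty(n_components)
    for i in range(n_components):
        vals = x[cell == i]
        sds[i] = max(vals.std(), 1e-6) if vals.size >= 10 else max(
            np.ptp(x) / (4.0 * n_components), 1e-6
        )
        weights[i] = max(vals.size, 1)
    weights = weights / weights.sum()

    prev = -np.inf
    for _ in range(n_iter):
        dens = weights * stats.norm.pdf(x[:, None], means[None, :], sds[None, :])
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, np.finfo(float).tiny)
        ll = float(np.sum(np.log(tot)))
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        weights = nk / n
        for i in free_idx:
            if nk[i] > 0:
                means[i] = float(resp[:, i] @ x / nk[i])
        for i in range(n_components):
            if nk[i] > 0:
                var = float(resp[:, i] @ (x - means[i]) ** 2 / nk[i])
                # same relative-width cap as the histogram backend
                cap = 0.5 * (anchors[i] if i in anchors else float(x.max()))
                sds[i] = min(max(np.sqrt(var), 1e-6), max(cap, 1e-6))
        if abs(ll - prev) < tol * (1 + abs(ll)):
            break
        prev = ll

    return [
        ECSComponent(
            ROMAN[i],
            float(means[i]),
            float(sds[i]),
            float(weights[i] * n * bin_width / (sds[i] * _SQRT2PI)),
            i in anchors,
        )
        for i in range(n_components)
    ]


def sequential_anchor_fit(
    samples, n_components=None, bins="fd", anchor_slack: float = 0.0, backend="histogram"
) -> list[ECSFitResult]:
    """Sequentially anchored fits across samples of increasing complexity.

    ``samples`` is an ordered list of ``(label, ecs_values)`` with the
    simplest assembly (monomer) first.  Sample ``k`` (1-based) is fitted
    with ``k`` components whose first ``k - 1`` means are anchored at the
    means fitted in the earlier samples; the monomer is fitted with a single
    free Gaussian.  If samples are passed in a different order, anchoring
    simply uses the means in the order given — the ordering is the caller's
    statement of assembly complexity.

    ``n_components`` optionally overrides the per-sample component count
    (list of ints, one per sample); each sample still anchors every
    previously identified mean that falls inside its data range.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    counts = n_components or [min(k + 1, 8) for k in range(len(samples))]
    if len(counts) != len(samples):
        raise ValueError("n_components must give one count per sample")

    fits: list[ECSFitResult] = []
    known_means: list[float] = []
    for (label, values), k in zip(samples, counts):
        values = np.asarray(values, dtype=float)
        usable = [m for m in known_means if values.min() <= m <= values.max()]
        anchors = [(i, m) for i, m in enumerate(usable[: k - 1])]
        try:
            fit = fit_ecs_distribution(
                values, k, anchors=anchors, bins=bins,
                anchor_slack=anchor_slack, backend=backend, sample_label=label,
            )
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"sample {label!r}: {exc}") from exc
        fits.append(fit)
        new = [c.mean for c in fit.components if not c.fixed_mean and c.mean not in known_means]
        if new:
            known_means.append(max(new))
            known_means.sort()
    return fits


def compute_yields(fit: ECSFitResult, target_label: str) -> YieldReport:
    """Assembly yields from the areas of the fitted Gaussian components.

    ``percent_i = 100 * area_i / sum(area)`` with
    ``area = amplitude * sd * sqrt(2*pi)``; ``target_label`` names the
    intended end product whose percentage is the sample's assembly yield.
    """
    areas = np.array([c.area for c in fit.components])
    if not np.any(areas > 0):
        raise ValueError("all component areas are zero; yields undefined")
    fit.component(target_label)  # raises KeyError if absent
    percents = 100.0 * areas / areas.sum()
    per_component = [(c.label, float(p)) for c, p in zip(fit.components, percents)]
    target = dict(per_component)[target_label]
    return YieldReport(
        sample_label=fit.sample_label,
        per_component=per_component,
        target_label=target_label,
        target_yield=target,
    )


def assign_events_to_components(events: EventTable, fit: ECSFitResult) -> EventTable:
    """Label each event with its most likely ECS component.

    The score for component ``i`` is ``amplitude_i * N(ecs; mean_i, sd_i)``;
    ties break toward the lower-mean component (conservatively calling
    unassembled monomer).  Returns a new :class:`EventTable` whose events
    frame carries a ``component`` column.
    """
    ecs = events.events["ecs"].to_numpy()
    scores = np.stack(
        [c.amplitude * stats.norm.pdf(ecs, c.mean, c.sd) for c in fit.components]
    )
    best = np.argmax(scores, axis=0)  # argmax takes the first (lower-mean) maximum
    labels = np.array([c.label for c in fit.components], dtype=object)
    frame = events.events.copy()
    frame["component"] = labels[best] if len(ecs) else np.array([], dtype=object)
    return EventTable(frame, events.sample_label, events.trace_duration)


def fit_ecs_vs_size(points) -> LinearECSModel:
    """OLS fit of mean ECS against the number of tiles in the assembly."""
    pts = [(float(n), float(e)) for n, e in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise ValueError("need at least 2 distinct assembly sizes")
    res = stats.linregress(xs, ys)
    return LinearECSModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def yield_repeatability(yields) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of repeated yield estimates."""
    ys = np.asarray(list(yields), dtype=float)
    if ys.size < 2:
        raise ValueError("need at least 2 repeated yields")
    return float(ys.mean()), float(ys.std(ddof=1))
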