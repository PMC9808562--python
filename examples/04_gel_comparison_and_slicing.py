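"""Benchmark nanopore yields against gel densitometry; slice events by state.

Computes size-corrected molar yields from an agarose-gel band-intensity
table (intensity / tiles-per-structure, normalised) and compares them with
nanopore-derived yields for the same samples.  Also demonstrates per-event
component assignment: slicing a dimer sample's events by their most likely
ECS component separates the residual monomers from the assembled dimers.
"""

import origamipore as op

# --- gel lanes: band intensities in arbitrary densitometry units ----------
lanes = [
    op.GelLaneTable("monomer", [("I", 120.0, 1)]),
    op.GelLaneTable("dimer", [("I", 55.0, 1), ("II", 170.0, 2)]),
]
gel_reports = [op.gel_yields(lane) for lane in lanes]
for rep in gel_reports:
    desc = ", ".join(f"{lab}={pct:.1f}%" for lab, pct in rep.per_component)
    print(f"gel {rep.sample_label:8s} {desc}")

# --- nanopore yields for the same two samples ------------------------------
species = {sp.name: sp for sp in op.calibrated_species()}
ecs_samples, tables = [], {}
for k, (label, mix) in enumerate(
    [("monomer", [("monomer", 1.0)]), ("dimer", [("monomer", 0.4), ("dimer", 0.6)])]
):
    config = op.GeneratorConfig(duration=90.0, seed=20 + k)
    comp = op.SampleComposition([(species[n], f) for n, f in mix])
    trace, _ = op.simulate_trace(config, comp, label=label)
    tables[label] = op.detect_events(trace, op.estimate_baseline(trace))
    ecs_samples.append((label, tables[label].events["ecs"].to_numpy()))
fits = op.sequential_anchor_fit(ecs_samples)
nano_reports = [op.compute_yields(fit, fit.components[-1].label) for fit in fits]
for rep in nano_reports:
    desc = ", ".join(f"{lab}={pct:.1f}%" for lab, pct in rep.per_component)
    print(f"pore {rep.sample_label:8s} {desc}")

table = op.compare_reports(nano_reports, gel_reports, margin=5.0)
print("\nmethod comparison (difference = nanopore - gel, flagged if |diff| > 5):")
print(table.to_string(index=False))

# --- slice the dimer events by ECS component -------------------------------
dimer_fit = fits[1]
labelled = op.assign_events_to_components(tables["dimer"], dimer_fit)
sliced = labelled.events.groupby("component")[["peak_max_pA", "dwell_ms", "ecs"]].mean()
print("\ndimer events sliced by ECS component (per-slice feature means):")
print(sliced.round(1).to_string())
print("The component-II slice has higher amplitude and longer dwell than the")
print("component-I slice: the residual-monomer population is cleanly separated.")
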