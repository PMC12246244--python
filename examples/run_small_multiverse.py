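"""Run a small multiverse: enumerate forking paths, execute, rank, perturb.

Varies four preprocessing steps (16 paths) over an eight-participant study,
ranks paths by their total T-sum, and shows the effect of substituting one
single step relative to a reference path.
"""

import eegmultiverse as emv

cfg = emv.default_config(n_participants=8, n_trials=(50, 50), seed=21)
recordings, _ = emv.generate_study(cfg)
prepared = [emv.prepare_recording(r) for r in recordings]

grid = {
    "ocular": ["none", "ica"],
    "muscle": ["none"],
    "lpf": ["none", "6"],
    "hpf": ["none"],
    "reference": ["Cz"],
    "detrend": ["none", "linear"],
    "baseline": ["none", "200ms"],
    "reject": ["none"],
}
print(f"full grid would have {emv.StepGrid().n_paths} paths; "
      f"this reduced grid has {emv.StepGrid(steps=grid).n_paths}")

table = emv.run_multiverse(prepared, grid, master_seed=7)

ranking = emv.rank_paths(table, metric="t_sum")
print("\nbest three forking paths by total T-sum:")
print(ranking.head(3).to_string(index=False))

ref = emv.ForkingPath.from_dict({
    "ocular": "ica", "muscle": "none", "lpf": "none", "hpf": "none",
    "reference": "Cz", "detrend": "none", "baseline": "200ms",
    "reject": "none"})
deltas = emv.substitute_single_step(table, grid, reference_path=ref)
print("\nsingle-step substitutions vs the reference path "
      "(positive delta = switching the level would improve the T-sum):")
print(deltas[["step", "level", "reference_level", "delta"]]
      .to_string(index=False))
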