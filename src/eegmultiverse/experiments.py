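"""Self-contained reproduction experiments.

Each function builds its own synthetic inputs, runs the relevant part of the
pipeline end to end, and returns the summary quantity it measures.  They are
the package's calibration experiments: family-wise error control of the
cluster mass test, T-sum/TFCE-sum concordance across a reduced multiverse,
and the directional effect of artifact correction on decoding performance
when artifacts covary with the condition.
"""

from __future__ import annotations

import numpy as np

from .cluster_stats import ClusterTestConfig, cluster_mass_test, tfce_sum
from .engine import (
    StepGrid,
    fractional_factorial,
    prepare_recording,
    run_multiverse,
    substitute_single_step,
    ForkingPath,
)
from .factorial import FactorialModelSpec, estimated_marginal_means, fit_factorial_lm
from .seeding import child_rng, child_seed
from .synth import ArtifactSpec, default_config, generate_study

__all__ = [
    "null_cluster_fwer", "REDUCED_GRID", "tsum_tfce_concordance",
    "artifact_correction_direction",
]


def null_cluster_fwer(n_studies: int = 200, n_participants: int = 20,
                      n_times: int = 100, noise_sd: float = 0.02,
                      seed: int = 0, n_permutations: int = 1024,
                      fwer_alpha: float = 0.05) -> float:
    """Empirical family-wise error rate of the cluster mass test under null.

    Simulates ``n_studies`` independent group datasets of chance-level
    balanced-accuracy time series (0.5 plus i.i.d. Gaussian noise), runs the
    sign-flip permutation cluster mass test on each, and returns the fraction
    of studies with at least one retained (significant) cluster — the
    empirical FWER, nominally ``fwer_alpha``.
    """
    rng = child_rng(seed, "fwer-null")
    times = np.arange(n_times) / 100.0
    hits = 0
    for i in range(n_studies):
        acc = 0.5 + noise_sd * rng.standard_normal((n_participants, n_times))
        cfg = ClusterTestConfig(n_permutations=n_permutations,
                                fwer_alpha=fwer_alpha,
                                seed=child_seed(seed, "fwer", i))
        res = cluster_mass_test(acc, times, cfg)
        hits += bool(res.significant_clusters)
    return hits / n_studies


#: Two levels per step — the reduced multiverse used for desk-scale runs.
REDUCED_GRID: dict[str, list[str]] = {
    "ocular": ["none", "ica"],
    "muscle": ["none", "ica"],
    "lpf": ["none", "6"],
    "hpf": ["none", "0.5"],
    "reference": ["Cz", "average"],
    "detrend": ["none", "linear"],
    "baseline": ["none", "200ms"],
    "reject": ["none", "interpolate"],
}


def tsum_tfce_concordance(seed: int = 0, n_participants: int = 6,
                          n_trials: int = 40, half_fraction: bool = True):
    """Pearson correlation between total T-sums and TFCE-sums across paths.

    Generates one synthetic study with planted condition effect and
    artifact/drift structure, runs a reduced multiverse spanning every
    preprocessing step (a half fraction of the two-level grid: 128 paths),
    and correlates the two decoding-performance summaries across paths.

    Returns ``(r, table)``.
    """
    cfg = default_config(n_participants=n_participants,
                         n_trials=(n_trials, n_trials),
                         seed=child_seed(seed, "concordance-study"))
    recs, _ = generate_study(cfg)
    prep = [prepare_recording(r) for r in recs]
    paths = (fractional_factorial(REDUCED_GRID) if half_fraction
             else None)
    table = run_multiverse(prep, paths if paths is not None
                           else StepGrid(steps=REDUCED_GRID),
                           master_seed=child_seed(seed, "concordance-run"),
                           compute_tfce=True)
    ts = table.group_metric("t_sum")
    tf = table.group_metric("tfce_sum").reindex(ts.index)
    r = float(np.corrcoef(ts.to_numpy(), tf.to_numpy())[0, 1])
    return r, table


def artifact_correction_direction(seed: int = 0, n_participants: int = 8,
                                  n_trials: int = 40, ocular_rho: float = 0.5):
    """Effect of ocular artifact correction when blinks covary with class.

    Runs a small multiverse varying ocular ICA against two context steps on a
    study with strongly condition-covarying blinks, fits the factorial model,
    and returns ``(emm_table, substitution_deltas)`` for the ocular step.
    When part of the decodable information rides on the artifact, correction
    removes it: EMM(none) > EMM(ica) and the single-step substitution deltas
    for switching ocular correction on are negative.
    """
    cfg = default_config(
        n_participants=n_participants, n_trials=(n_trials, n_trials),
        artifact_ocular=ArtifactSpec(rate=0.4, amplitude=120.0,
                                     class_cov=ocular_rho),
        seed=child_seed(seed, "direction-study"))
    recs, _ = generate_study(cfg)
    prep = [prepare_recording(r) for r in recs]
    grid = {"ocular": ["none", "ica"], "hpf": ["none", "0.5"],
            "baseline": ["none", "200ms"]}
    table = run_multiverse(prep, StepGrid(steps=grid),
                           master_seed=child_seed(seed, "direction-run"))
    model = fit_factorial_lm(table.group_metric("t_sum"), grid,
                             FactorialModelSpec(response="t_sum"))
    emm = estimated_marginal_means(model, "ocular")
    ref = ForkingPath.from_dict({"ocular": "none", "hpf": "0.5",
                                 "baseline": "200ms"})
    deltas = substitute_single_step(table, grid, reference_path=ref,
                                    metric="t_sum")
    return emm, deltas
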