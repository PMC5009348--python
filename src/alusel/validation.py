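"""Built-in validation experiments.

These functions run the package's simulators and statistics end to end at
the fixed study conditions and summarize the outcomes that the method's
credibility rests on: parameter recovery for the differentiation model and
the sweep-versus-neutral contrast for the haplotype and SFS statistics.
"""

from __future__ import annotations

import numpy as np

from .popgen import (
    _informative_sites,
    daf,
    faywu_h,
    fst_wc_multilocus,
    ihs_standardize,
    ihs_unstandardized,
    tajimas_d,
    window_sfs,
)
from .simulate import (
    PopSimConfig,
    simulate_balding_nichols,
    simulate_wright_fisher,
    sweep_study_config,
)

__all__ = ["bn_recovery_study", "sweep_detection_study"]


def bn_recovery_study(seed: int, F_values=(0.1, 0.3)) -> dict[float, float]:
    """Recover Balding–Nichols F by multi-locus Weir–Cockerham theta.

    Study conditions: 3 populations x 100 diploids, 500 independent SNPs.
    """
    out = {}
    for F in F_values:
        panel = simulate_balding_nichols(
            PopSimConfig(F=F, diploids_per_pop=100, n_snps=500, seed=seed)
        )
        out[F] = fst_wc_multilocus(panel)
    return out


def sweep_detection_study(
    seed: int,
    n_neutral: int = 20,
    n_sweep: int = 5,
    s: float = 0.05,
    window_bp: int = 30_000,
    n_bins: int = 30,
) -> dict:
    """Neutral-versus-sweep contrast at the fixed sweep study conditions.

    Runs ``n_neutral`` neutral replicates and ``n_sweep`` replicates with an
    additive sweep (coefficient ``s``, onset generation 5, population CHB,
    sampled at derived frequency 0.88) and summarizes:

    * windowed Fay–Wu's H at the region center: neutral 5th percentile vs
      the sweep replicates' median;
    * standardized |iHS| at the swept site vs the neutral 95th percentile
      (u values from all three populations of the neutral replicates feed
      the empirical frequency-bin standardization);
    * mean neutral Tajima's D (sanity: equilibrium demography, ~0).
    """
    center = sweep_study_config(0).chromosome_length // 2
    neutral_h, neutral_d = [], []
    neutral_u, neutral_daf = [], []
    base = (seed * 9973) % (2**31 - 1)
    for k in range(n_neutral):
        panel = simulate_wright_fisher(sweep_study_config(base + k + 1))
        sfs = window_sfs(panel, "CHB", center, window_bp)
        h = faywu_h(sfs)
        d = tajimas_d(sfs)
        if h == h:
            neutral_h.append(h)
        if d == d:
            neutral_d.append(d)
        near = np.flatnonzero(np.abs(panel.positions - center) < 50_000)
        for pop in ("CEU", "CHB", "YRI"):
            informative = _informative_sites(panel, pop, 0.05)
            for i in near[::2]:
                u = ihs_unstandardized(panel, pop, int(i), _informative=informative)
                if u == u:
                    neutral_u.append(u)
                    neutral_daf.append(daf(panel, int(i), pop))
    sweep_h, sweep_u, sweep_daf = [], [], []
    for k in range(n_sweep):
        cfg = sweep_study_config(
            base + 1000 + k, selection=("CHB", s, 5)
        )
        panel = simulate_wright_fisher(cfg)
        i = int(np.argmin(np.abs(panel.positions - center)))
        sweep_h.append(faywu_h(window_sfs(panel, "CHB", center, window_bp)))
        sweep_u.append(ihs_unstandardized(panel, "CHB", i))
        sweep_daf.append(daf(panel, i, "CHB"))
    all_u = np.array(neutral_u + sweep_u)
    all_daf = np.array(neutral_daf + sweep_daf)
    z = ihs_standardize(all_u, all_daf, n_bins=n_bins)
    z_neutral = np.abs(z[: len(neutral_u)])
    z_sweep = np.abs(z[len(neutral_u):])
    return {
        "neutral_mean_tajima_d": float(np.mean(neutral_d)),
        "neutral_h_p5": float(np.percentile(neutral_h, 5)),
        "sweep_h_median": float(np.median(sweep_h)),
        "sweep_h": [float(x) for x in sweep_h],
        "neutral_absz_p95": float(np.nanpercentile(z_neutral, 95)),
        "sweep_absz_median": float(np.nanmedian(z_sweep)),
        "sweep_absz": [float(x) for x in z_sweep],
        "sweep_daf": [float(x) for x in sweep_daf],
        "n_neutral_u": int(len(neutral_u)),
    }
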