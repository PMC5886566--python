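"""Simulation-based self-checks: does the pipeline recover what was injected?

Each function runs the full measurement path (simulate, filter, score) over
many independent seeds and reports how the pipeline's estimates relate to
the generator's truth:

* ``epsilon_recovery`` — the observed discordance fraction Ndi/NPos versus
  the injected per-position discordance probability, with the fraction of
  seeds falling inside the 3-binomial-SE band, plus the FFPE-private
  C>T/G>A artifact-rate estimate from the same simulated pairs;
* ``overlap_recovery`` — the mean FF/FFPE somatic overlap versus the
  independent-detection expectation n_somatic * det_ff * det_ffpe.

Seeds are spawned deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .concordance import pair_summary
from .simulate import SimulationConfig, simulate_pair, simulate_tumor_normal
from .somatic import condition_overlap, tumor_specific
from .variant_io import SNV, apply_quality_filter


def _seeds(master_seed: int, n: int) -> list[int]:
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n).tolist()


def epsilon_recovery(
    cfg: Optional[SimulationConfig] = None,
    n_seeds: int = 200,
    master_seed: int = 20_170_425,
) -> dict:
    """Discordance and artifact-rate recovery over ``n_seeds`` simulations.

    For each seed a full FF/FFPE pair is simulated, quality-filtered and
    scored; the SNV discordance fraction Ndi/NPos is compared with the
    injected probability, counting seeds within 3*sqrt(eps*(1-eps)/NPos).
    The FFPE-private C>T/G>A call count from the same pair estimates the
    artifact injection rate.
    """
    cfg = cfg or SimulationConfig()
    eps = cfg.discordance_prob
    in_band = 0
    ratios, ndis, art_rates = [], [], []
    for seed in _seeds(master_seed, n_seeds):
        scfg = dataclasses.replace(cfg, seed=seed)
        ff, ffpe, ledger = simulate_pair(scfg)
        ff_f, ffpe_f = apply_quality_filter(ff), apply_quality_filter(ffpe)
        pc = pair_summary(ff_f, ffpe_f, SNV, pair_id=str(seed))
        ratio = pc.n_di / pc.n_pos
        se = math.sqrt(eps * (1 - eps) / pc.n_pos)
        in_band += abs(ratio - eps) <= 3 * se
        ratios.append(ratio)
        ndis.append(pc.n_di)
        # FFPE-private C>T / G>A calls estimate the injected artifact rate
        n_art = sum(
            1
            for key, rec in ffpe_f.records.items()
            if key not in ff_f.records
            and rec.vclass == SNV
            and (rec.ref, rec.alts[0]) in (("C", "T"), ("G", "A"))
        )
        art_rates.append(n_art / cfg.n_germline)
    art = np.asarray(art_rates)
    return dict(
        n_seeds=n_seeds,
        epsilon=eps,
        coverage_fraction=in_band / n_seeds,
        mean_ndi=float(np.mean(ndis)),
        mean_ratio=float(np.mean(ratios)),
        artifact_rate_true=cfg.artifact_rate,
        artifact_rate_mean=float(art.mean()),
        artifact_rate_se=float(art.std(ddof=1) / math.sqrt(n_seeds)),
    )


def overlap_recovery(
    cfg: Optional[SimulationConfig] = None,
    n_seeds: int = 200,
    master_seed: int = 20_170_425,
) -> dict:
    """Mean somatic FF/FFPE overlap versus n_somatic * det_ff * det_ffpe."""
    cfg = cfg or SimulationConfig(
        n_germline=500, n_somatic=400, det_ff=0.5, det_ffpe=0.5
    )
    overlaps = []
    for seed in _seeds(master_seed, n_seeds):
        scfg = dataclasses.replace(cfg, seed=seed)
        t_ff, n_ff, t_ffpe, n_ffpe, _ = simulate_tumor_normal(scfg)
        comp = condition_overlap(
            tumor_specific(apply_quality_filter(t_ff).subset(SNV),
                           apply_quality_filter(n_ff).subset(SNV)),
            tumor_specific(apply_quality_filter(t_ffpe).subset(SNV),
                           apply_quality_filter(n_ffpe).subset(SNV)),
        )
        overlaps.append(comp.n_overlap)
    arr = np.asarray(overlaps, float)
    return dict(
        n_seeds=n_seeds,
        expected=cfg.n_somatic * cfg.det_ff * cfg.det_ffpe,
        mean_overlap=float(arr.mean()),
        se=float(arr.std(ddof=1) / math.sqrt(n_seeds)),
    )
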