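"""Recovery studies and calibration checks on synthetic cohorts.

Each function runs one self-contained validation study of the pipeline —
Monte-Carlo-vs-exhaustive Mantel agreement, null calibration of the
interaction network, planted-coupling detection power, stage-dynamics
signature recovery, deconvolution accuracy, statistical-primitive oracles,
and end-to-end determinism — and returns a small dict of measured
quantities.  The studies are sized to run on a single CPU in a few minutes;
problem sizes mirror the emulated cohort design (3 stages of ~28-30
samples, 10 cell types, five 20-gene death programs, 10% multiplicative
noise).
"""

from __future__ import annotations

import dataclasses
import tempfile
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .deconvolution import estimate_proportions, evaluate_recovery
from .dynamics import classify_changes, count_interactions
from .interactions import (
    DistanceMatrix,
    build_interaction_network,
    mantel_test,
    mantel_test_exhaustive,
)
from .io import PipelineConfig, counts_to_tpm
from .pipeline import run_all
from .synthetic import CohortConfig, PlantedCoupling, generate_cohort

__all__ = [
    "mantel_oracle_study",
    "null_calibration_study",
    "planted_power_study",
    "dynamics_recovery_study",
    "deconvolution_recovery_study",
    "primitive_oracle_study",
    "determinism_study",
]


def _child_seeds(seed: int, n: int, label: str) -> list[int]:
    import hashlib

    key = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _random_distance_pair(rng: np.random.Generator, n: int):
    ids = [f"S{i}" for i in range(n)]
    return (DistanceMatrix(ids, pdist(rng.normal(size=(n, 3)))),
            DistanceMatrix(ids, pdist(rng.normal(size=(n, 3)))))


def _brute_force_exact_p(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Plain-loop enumeration oracle, independent of the package's gather."""
    sq2 = d2.square()
    r_obs = np.corrcoef(d1.condensed, d2.condensed)[0, 1]
    hits = total = 0
    for perm in permutations(range(d1.n)):
        permuted = squareform(sq2[np.ix_(perm, perm)], checks=False)
        hits += np.corrcoef(d1.condensed, permuted)[0, 1] >= r_obs - 1e-12
        total += 1
    return hits / total


def mantel_oracle_study(seed: int = 0, n_instances: int = 100,
                        n_perm: int = 1000) -> dict:
    """Exhaustive-vs-brute-force agreement and Monte-Carlo convergence.

    For random instances with 4-6 samples: the exhaustive p must equal an
    independent enumeration exactly, and the Monte-Carlo p must lie within
    3 Monte-Carlo standard errors of it (plus the add-one offset).
    """
    rng = np.random.default_rng(seed)
    max_exact_dev = 0.0
    max_mc_dev_units = 0.0
    for i in range(n_instances):
        n = int(rng.choice([4, 5, 6]))
        d1, d2 = _random_distance_pair(rng, n)
        _, p_exact = mantel_test_exhaustive(d1, d2)
        p_bf = _brute_force_exact_p(d1, d2)
        max_exact_dev = max(max_exact_dev, abs(p_exact - p_bf))
        _, p_mc = mantel_test(d1, d2, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        mcse = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        slack = 1.0 / (n_perm + 1)  # add-one bias bound
        if mcse > 0:
            max_mc_dev_units = max(max_mc_dev_units,
                                   (abs(p_mc - p_exact) - slack) / mcse)
    return {
        "max_exact_oracle_abs_dev": float(max_exact_dev),
        "max_mc_dev_mcse_units": float(max_mc_dev_units),
        "n_instances": n_instances,
    }


def _network_for_cohort(config: CohortConfig, pipeline: PipelineConfig):
    cohort = generate_cohort(config)
    tpm = counts_to_tpm(cohort.counts, cohort.annotation)
    proportions = estimate_proportions(tpm, cohort.truth.signature_matrix)
    records = build_interaction_network(tpm, proportions, cohort.catalog,
                                        cohort.metadata, pipeline)
    return cohort, records


def null_calibration_study(seed: int = 0, n_pairs: int = 2000,
                           n_perm: int = 1000) -> dict:
    """Raw Mantel p-values under no coupling should be uniform, and the
    BH-flagged fraction should stay at the nominal level."""
    per_cohort = 2 * 5 * 10  # 2 stages x 5 modes x 10 types
    n_cohorts = int(np.ceil(n_pairs / per_cohort))
    p_values, flags = [], []
    for s in _child_seeds(seed, n_cohorts, "null"):
        config = CohortConfig(
            n_samples_per_stage={"BLB0": 30, "BLB6": 30},
            n_genes_background=400, rng_seed=s)
        _, records = _network_for_cohort(
            config, PipelineConfig(n_permutations=n_perm, rng_seed=s))
        p_values.extend(records["p_value"])
        flags.extend(records["significant"])
    p_values = np.asarray(p_values[:n_pairs])
    flags = np.asarray(flags[:n_pairs], bool)
    ks_p = float(stats.kstest(p_values, "uniform").pvalue)
    return {
        "ks_uniformity_p": ks_p,
        "bh_flag_rate": float(flags.mean()),
        "mcse": float(np.sqrt(0.05 * 0.95 / len(flags))),
        "n_pairs": int(len(p_values)),
    }


def planted_power_study(seed: int = 0, n_seeds: int = 100,
                        n_per_stage: int = 28, beta: float = 0.8) -> dict:
    """Detection power for one strong last-stage necroptosis-neuron coupling.

    Power = fraction of seeded cohorts in which the targeted record is
    BH-significant with positive Mantel R; also reports the worst off-target
    flag rate over all other (stage, mode, type) records.
    """
    hits = 0
    off_counts: dict[tuple, int] = {}
    for s in _child_seeds(seed, n_seeds, "power"):
        config = CohortConfig(
            n_samples_per_stage={"BLB0": n_per_stage, "BLB5": n_per_stage,
                                 "BLB6": n_per_stage},
            coupling_specs=(PlantedCoupling("BLB6", "necroptosis",
                                            "neurons", beta),),
            rng_seed=s)
        _, records = _network_for_cohort(config, PipelineConfig(rng_seed=s))
        target = records[(records.stage == "BLB6")
                         & (records.death_mode == "necroptosis")
                         & (records.cell_type == "neurons")]
        hits += bool(target.significant.iloc[0]) and target.mantel_r.iloc[0] > 0
        off = records.drop(target.index)
        for _, row in off[off.significant].iterrows():
            key = (row.stage, row.death_mode, row.cell_type)
            off_counts[key] = off_counts.get(key, 0) + 1
    max_off_rate = max(off_counts.values()) / n_seeds if off_counts else 0.0
    return {
        "power": hits / n_seeds,
        "max_offtarget_flag_rate": float(max_off_rate),
        "n_seeds": n_seeds,
    }


def dynamics_recovery_study(seed: int = 0, n_seeds: int = 100,
                            n_per_stage: int = 30) -> dict:
    """Recovery of the qualitative stage signature: a necroptosis coupling
    growing (0 -> 0.4 -> 0.8) and a ferroptosis coupling shrinking
    (0.8 -> 0.4 -> 0) should read out as a net increase and a net decrease
    of significant interaction counts, respectively."""
    stages = ("BLB0", "BLB5", "BLB6")
    necro_ok = ferro_ok = both_ok = 0
    for s in _child_seeds(seed, n_seeds, "dynamics"):
        couplings = (
            PlantedCoupling("BLB5", "necroptosis", "neurons", 0.4),
            PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),
            PlantedCoupling("BLB0", "ferroptosis", "microglia", 0.8),
            PlantedCoupling("BLB5", "ferroptosis", "microglia", 0.4),
        )
        config = CohortConfig(
            n_samples_per_stage={st: n_per_stage for st in stages},
            coupling_specs=couplings, rng_seed=s)
        _, records = _network_for_cohort(config, PipelineConfig(rng_seed=s))
        summary = count_interactions(records, stages)
        changes = classify_changes(summary, stages)
        net = changes.groupby("mode")["delta"].sum()
        n_up = net.get("necroptosis", 0) > 0
        f_down = net.get("ferroptosis", 0) < 0
        necro_ok += n_up
        ferro_ok += f_down
        both_ok += n_up and f_down
    return {
        "recovery_rate": both_ok / n_seeds,
        "necroptosis_increase_rate": necro_ok / n_seeds,
        "ferroptosis_decrease_rate": ferro_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def deconvolution_recovery_study(seed: int = 0, n_seeds: int = 20) -> dict:
    """Exactness on noiseless mixtures and accuracy at 10% noise."""
    noiseless = CohortConfig(
        n_samples_per_stage={"BLB0": 10, "BLB6": 10}, n_genes_background=300,
        noise_cv=0.0, count_noise="none",
        rng_seed=_child_seeds(seed, 1, "deconv0")[0])
    cohort = generate_cohort(noiseless)
    tpm = counts_to_tpm(cohort.counts, cohort.annotation)
    est = estimate_proportions(tpm, cohort.truth.signature_matrix)
    max_abs_err = float(np.max(np.abs(est.values
                                      - cohort.truth.true_proportions.values)))

    est_frames, true_frames = [], []
    for s in _child_seeds(seed, n_seeds, "deconv"):
        config = CohortConfig(
            n_samples_per_stage={"BLB0": 25, "BLB6": 25},
            n_genes_background=300, noise_cv=0.1, rng_seed=s)
        cohort = generate_cohort(config)
        tpm = counts_to_tpm(cohort.counts, cohort.annotation)
        est = estimate_proportions(tpm, cohort.truth.signature_matrix)
        est_frames.append(est.data.to_numpy())
        true_frames.append(cohort.truth.true_proportions.values)
    est_all = np.vstack(est_frames)
    true_all = np.vstack(true_frames)
    per_type_r = [float(np.corrcoef(est_all[:, j], true_all[:, j])[0, 1])
                  for j in range(est_all.shape[1])]
    return {
        "noiseless_max_abs_error": max_abs_err,
        "min_per_type_pearson_r": float(min(per_type_r)),
        "n_seeds": n_seeds,
    }


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def primitive_oracle_study(seed: int = 0) -> dict:
    """Brute-force oracles for BH, hypergeometric ORA, AUC and PCoA/PCA."""
    from sklearn.decomposition import PCA
    from statsmodels.stats.multitest import multipletests

    from .biomarker import roc_curve
    from .expression import ora_enrichment, pcoa
    from .io import ExpressionMatrix, GeneSetCatalog

    rng = np.random.default_rng(seed)

    bh_dev = 0.0
    for _ in range(1000):
        p = rng.uniform(size=rng.integers(2, 60))
        bh_dev = max(bh_dev, float(np.max(np.abs(
            multipletests(p, method="fdr_bh")[1] - _bh_oracle(p)))))

    ora_dev = 0.0
    for _ in range(20):
        m = int(rng.integers(8, 16))
        universe = [f"g{i}" for i in range(m)]
        set_genes = list(rng.choice(universe, size=rng.integers(2, m // 2 + 1),
                                    replace=False))
        deg = list(rng.choice(universe, size=rng.integers(1, m // 2 + 1),
                              replace=False))
        catalog = GeneSetCatalog()
        catalog.add("s", set_genes)
        res = ora_enrichment(deg, catalog, universe)
        k_obs = len(set(deg) & set(set_genes))
        hits = total = 0
        for draw in combinations(universe, len(deg)):
            total += 1
            hits += len(set(draw) & set(set_genes)) >= k_obs
        ora_dev = max(ora_dev, abs(float(res.p_value.iloc[0]) - hits / total))

    auc_dev = 0.0
    for _ in range(1000):
        n = int(rng.integers(6, 40))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)
        labels = rng.binomial(1, 0.5, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_curve(scores, labels)
        pairs_conc = 0.0
        pos, neg = scores[labels == 1], scores[labels == 0]
        for sp in pos:
            pairs_conc += np.sum(sp > neg) + 0.5 * np.sum(sp == neg)
        auc_dev = max(auc_dev, abs(res.auc - pairs_conc / (len(pos) * len(neg))))

    toy = roc_curve(np.arange(1, 7), np.array([0, 0, 1, 0, 1, 1]))

    raw = rng.lognormal(3, 1, (12, 8))
    tpm = ExpressionMatrix(pd.DataFrame(
        raw / raw.sum(axis=0) * 1e6,
        index=[f"g{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)]), "TPM")
    coords = pcoa(tpm, k=4).coordinates.to_numpy()
    scores_pca = PCA(n_components=4).fit_transform(np.log10(tpm.values + 1).T)
    pcoa_dev = float(np.max(np.abs(np.abs(coords) - np.abs(scores_pca))))

    return {
        "bh_oracle_max_abs_dev": bh_dev,
        "ora_oracle_max_abs_dev": float(ora_dev),
        "auc_pair_count_max_abs_dev": float(auc_dev),
        "auc_six_sample_toy": float(toy.auc),
        "pcoa_vs_pca_max_abs_dev": pcoa_dev,
    }


def determinism_study(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Two pipeline runs with one manifest must agree byte-for-byte on
    every output table."""
    pipeline = PipelineConfig(n_permutations=199, rng_seed=seed)
    cohort = CohortConfig(
        n_samples_per_stage={"BLB0": 8, "BLB5": 8, "BLB6": 8},
        n_genes_background=150, genes_per_death_set=10,
        coupling_specs=(PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),))
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        out_a = run_all(pipeline, Path(tmp) / "a",
                        cohort_config=dataclasses.replace(cohort))
        out_b = run_all(pipeline, Path(tmp) / "b",
                        cohort_config=dataclasses.replace(cohort))
        tables = sorted(p.name for p in out_a.iterdir()
                        if p.suffix in (".tsv", ".gmt"))
        identical = all((out_a / name).read_bytes() == (out_b / name).read_bytes()
                        for name in tables)
    return {"identical": bool(identical), "n_tables": len(tables)}
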