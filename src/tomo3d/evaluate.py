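"""Accuracy and screening statistics for reconstructed volumes.

Reconstruction accuracy is the Pearson correlation coefficient (PCC)
between a reconstruction and its ground truth, computed over mask voxels
only — voxels outside the sample carry no information and are excluded.
Significance comes from a permutation null: the reconstruction's values
are shuffled across mask voxels, the PCC recomputed, and the observed
PCCs compared with the pooled null by a two-sample Kolmogorov-Smirnov
test.  Screening statistics (Moran's I spatial autocorrelation with
6-connected, row-standardized weights restricted to the mask, and
correlation with a chosen target gene) rank genes by how regionalized or
how target-like their reconstructed patterns are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Mask3D
from .preprocess import compute_mask_marginals, common_scale, \
    intersection_normalize
from .reconstruct import IPFConfig, ipf_fit
from .simulate import SimulationTruth


@dataclass
class EvaluationReport:
    """Per-gene accuracy: observed PCC, permutation null, and p-values."""

    gene_id: str
    pcc: float
    null_pccs: np.ndarray
    empirical_p: float
    ks_statistic: float
    ks_p: float
    n_perm: int
    seed: int


@dataclass
class SpatialWeights:
    """Weight scheme for Moran's I: 6-connected 3D adjacency in the mask."""

    scheme: str = "rook6"
    row_standardized: bool = True
    restricted_to_mask: bool = True

    def __post_init__(self):
        if self.scheme != "rook6":
            raise ValueError(f"unsupported weight scheme: {self.scheme!r}")
        if not self.restricted_to_mask:
            raise ValueError("weights must be restricted to the mask")


def pcc_masked(recon: np.ndarray, truth: np.ndarray, mask: Mask3D,
               ) -> float:
    """Pearson correlation over mask-1 voxels; NaN if either side is
    constant there (correlation undefined)."""
    support = mask.values.astype(bool)
    a = np.asarray(recon, dtype=float)[support]
    b = np.asarray(truth, dtype=float)[support]
    if a.size < 2:
        raise ValueError("need at least 2 mask voxels for a correlation")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def randomization_test(recon: np.ndarray, truth: np.ndarray, mask: Mask3D,
                       n_perm: int = 1000, seed: int = 0,
                       ) -> EvaluationReport:
    """Permutation null for the masked PCC.

    The reconstruction's values are permuted across mask voxels (values
    outside the mask take no part); each permutation's PCC against the
    unshuffled truth forms the null sample.  The empirical p-value uses the
    add-one convention (1 + #{null >= observed}) / (n_perm + 1); a one-gene
    KS test against its own null is also reported.
    """
    observed = pcc_masked(recon, truth, mask)
    if np.isnan(observed):
        raise ValueError("observed PCC undefined (constant field over mask); "
                         "randomization test aborted")
    support = mask.values.astype(bool)
    a = np.asarray(recon, dtype=float)[support]
    b = np.asarray(truth, dtype=float)[support]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = (rng.permutation(a) @ b) / denom
    empirical_p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    ks_stat, ks_p = ks_compare(np.array([observed]), null)
    return EvaluationReport(gene_id="", pcc=observed, null_pccs=null,
                            empirical_p=empirical_p, ks_statistic=ks_stat,
                            ks_p=ks_p, n_perm=n_perm, seed=seed)


def ks_compare(observed_pccs: np.ndarray, null_pccs: np.ndarray,
               ) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    observed_pccs = np.asarray(observed_pccs)
    null_pccs = np.asarray(null_pccs)
    if observed_pccs.size == 0 or null_pccs.size == 0:
        raise ValueError("KS comparison requires non-empty samples")
    res = stats.ks_2samp(observed_pccs, null_pccs, method="asymp")
    return float(res.statistic), float(res.pvalue)


def morans_i(volume: np.ndarray, mask: Mask3D,
             weights: SpatialWeights | None = None) -> float:
    """Moran's I over mask voxels with 6-connected neighbor weights.

    I = (N / sum of weights) * sum_ij w_ij z_i z_j / sum_i z_i^2 with
    z the mask-voxel values centered on their mean.  Row-standardized
    weights give each voxel's neighbors equal total weight 1; the null
    expectation for a spatially random field is -1/(N-1).  NaN for a
    constant field.
    """
    weights = weights or SpatialWeights()
    support = mask.values.astype(bool)
    v = np.asarray(volume, dtype=float)
    N = int(support.sum())
    if N < 2:
        raise ValueError("need at least 2 mask voxels")
    z = np.where(support, v - v[support].mean(), 0.0)
    ss = float((z[support] ** 2).sum())
    if ss == 0:
        return float("nan")

    # neighbor sums and degrees via the six face shifts
    nbr_sum = np.zeros_like(z)
    degree = np.zeros(z.shape)
    for axis in range(3):
        for direction in (1, -1):
            shifted_z = np.roll(z, direction, axis=axis)
            shifted_m = np.roll(support, direction, axis=axis)
            # rolled-around entries are not real neighbors
            edge = [slice(None)] * 3
            edge[axis] = 0 if direction == 1 else -1
            shifted_z[tuple(edge)] = 0.0
            shifted_m = shifted_m.copy()
            shifted_m[tuple(edge)] = False
            nbr_sum += np.where(shifted_m, shifted_z, 0.0)
            degree += shifted_m
    degree *= support

    if weights.row_standardized:
        has_nbr = support & (degree > 0)
        S = float((z[has_nbr] * nbr_sum[has_nbr] / degree[has_nbr]).sum())
        W = float(has_nbr.sum())
    else:
        S = float((z[support] * nbr_sum[support]).sum())
        W = float(degree[support].sum())
    if W == 0:
        return float("nan")
    return (N / W) * S / ss


def correlate_with_target(reconstructions: dict[str, np.ndarray],
                          target_gene: str, mask: Mask3D,
                          top_k: int = 4) -> pd.DataFrame:
    """Rank genes by masked PCC with the target gene's volume.

    Returns a DataFrame (gene_id, pcc, rank, in_top_k) sorted by descending
    PCC, ties broken lexicographically by gene ID; the target itself is
    excluded from the ranking.
    """
    if target_gene not in reconstructions:
        raise KeyError(f"target gene {target_gene!r} not among reconstructions")
    others = {g: v for g, v in reconstructions.items() if g != target_gene}
    if not others:
        raise ValueError("need at least one gene besides the target")
    target = reconstructions[target_gene]
    support = mask.values.astype(bool)
    if np.ptp(np.asarray(target, dtype=float)[support]) == 0:
        raise ValueError(f"target gene {target_gene!r} is constant over the mask")
    rows = [(g, pcc_masked(v, target, mask)) for g, v in others.items()]
    df = pd.DataFrame(rows, columns=["gene_id", "pcc"])
    df = df.sort_values(["pcc", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["in_top_k"] = df["rank"] <= top_k
    return df


def evaluate_simulation(truths: list[SimulationTruth],
                        config: IPFConfig | None = None,
                        n_perm: int = 1000, seed: int = 0,
                        normalize: bool = True,
                        ) -> tuple[pd.DataFrame, dict[str, list[EvaluationReport]]]:
    """Score reconstruction accuracy across simulated replicates.

    For each replicate and spatial gene: preprocess (inter-section
    normalization on by default), fit by IPF, compute the masked PCC
    against the truth volume and its permutation null.  Returns a summary
    table (one row per spatial gene: mean and sd of PCC across replicates,
    pooled-null KS statistic and p-value, worst empirical p) plus the
    per-replicate reports.
    """
    config = config or IPFConfig()
    reports: dict[str, list[EvaluationReport]] = {}
    for truth in truths:
        mask = truth.mask
        dataset = truth.dataset
        if normalize:
            marginals = compute_mask_marginals(mask)
            normalized = intersection_normalize(dataset, marginals)
        else:
            normalized = dataset
        for gene_id, E in truth.truth_volumes.items():
            vectors = common_scale(dataset, normalized, gene_id)
            recon = ipf_fit(vectors, mask, config)
            rep_seed = (seed * 100003 + truth.replicate_index * 1009
                        + len(reports.get(gene_id, []))) % (2 ** 31)
            report = randomization_test(recon.values, E, mask,
                                        n_perm=n_perm, seed=rep_seed)
            report.gene_id = gene_id
            reports.setdefault(gene_id, []).append(report)

    rows = []
    for gene_id, reps in reports.items():
        pccs = np.array([r.pcc for r in reps])
        pooled_null = np.concatenate([r.null_pccs for r in reps])
        ks_stat, ks_p = ks_compare(pccs, pooled_null)
        rows.append({
            "gene_id": gene_id,
            "n_replicates": len(reps),
            "pcc_mean": pccs.mean(),
            "pcc_sd": pccs.std(ddof=1) if len(reps) > 1 else 0.0,
            "ks_statistic": ks_stat,
            "ks_p": ks_p,
            "max_empirical_p": max(r.empirical_p for r in reps),
        })
    return pd.DataFrame(rows), reports
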