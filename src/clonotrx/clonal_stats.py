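"""Clonal-dynamics statistics over abundance matrices.

Covers the descriptive and inferential statistics applied to FACS-scaled
clonal abundance data: Shannon diversity per sample, cross-tissue Pearson
correlation of clonal composition, blood-vs-spleen-anchored 99%-CI tissue
bias calls, k-means classification of serial-transplant trajectories into
expanding/diminishing clones, and treatment-response comparisons
(log2 fold differences and per-clone Kruskal-Wallis tests with Bonferroni
correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.cluster import KMeans

__all__ = [
    "DiversityResult",
    "shannon_diversity",
    "pearson_cross_tissue",
    "tissue_bias",
    "classify_trajectories",
    "treatment_log2fc",
    "clone_response_test",
]

#: z quantile for a 99% two-sided normal interval
Z_99 = 2.576

#: pseudo-abundance floor for log ratios: one tenth of the detection threshold
ABUNDANCE_FLOOR = 0.001


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float
    n_clones: int


def shannon_diversity(abundances, sample_id: str = "", base: float = 2.0) -> DiversityResult:
    """Shannon diversity index of one sample's clone abundances (bits by default).

    Zero-abundance clones are dropped; the remaining abundances are
    renormalized to proportions.  0 <= H <= log_base(n_clones), with equality
    iff the composition is uniform.
    """
    a = np.asarray(pd.Series(abundances, dtype=float))
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all abundances are zero")
    h = float(_skbio_shannon(a, base=base))
    return DiversityResult(sample_id=sample_id, shannon=h, n_clones=int(a.size))


def pearson_cross_tissue(matrix: pd.DataFrame,
                         samples: Sequence[str] | None = None,
                         log_space: bool = False,
                         floor: float = ABUNDANCE_FLOOR) -> pd.DataFrame:
    """Pairwise Pearson correlation of clonal abundance between samples.

    Each pair is correlated over the union of clones detected (> 0) in
    either sample, with absent clones counted as 0 — this matches comparing
    whole clonal compositions rather than only shared clones.  Zero-variance
    vectors give NaN entries.  ``log_space`` correlates log10(a + floor)
    instead of raw percentages.
    """
    if samples is None:
        samples = list(matrix.index)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    sub = matrix.loc[list(samples)]
    n = len(samples)
    out = pd.DataFrame(np.eye(n), index=samples, columns=samples)
    for i in range(n):
        for j in range(i + 1, n):
            x = sub.iloc[i].to_numpy(float)
            y = sub.iloc[j].to_numpy(float)
            union = (x > 0) | (y > 0)
            if union.sum() < 2:
                r = np.nan
            else:
                xv, yv = x[union], y[union]
                if log_space:
                    xv = np.log10(xv + floor)
                    yv = np.log10(yv + floor)
                if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                    r = np.nan
                else:
                    r = float(stats.pearsonr(xv, yv).statistic)
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def tissue_bias(matrix: pd.DataFrame, blood_sample: str, spleen_sample: str,
                target_sample: str, floor: float = ABUNDANCE_FLOOR,
                z: float = Z_99, empirical_band: bool = False) -> pd.DataFrame:
    """Call clones biased toward a target tissue relative to the blood.

    Unbiased clones are assumed equally abundant across tissues, so the
    spread of log2 abundance ratios between two well-mixed compartments —
    blood and spleen — calibrates a null band.  The reference distribution is
    d_i = log2((a_spleen,i + floor) / (a_blood,i + floor)) over clones
    detected in blood or spleen; the band is mean(d) +/- z * sd(d) with
    z = 2.576 (99% normal interval) or, with ``empirical_band``, the
    0.5%/99.5% empirical quantiles.  Each clone detected in the target or
    blood is then called:

    * ``tissue_biased`` if its target-vs-blood log2 ratio exceeds the band,
    * ``blood_biased`` if below the band,
    * ``unbiased`` otherwise.
    """
    for s in (blood_sample, spleen_sample, target_sample):
        if s not in matrix.index:
            raise ValueError(f"sample {s!r} not in abundance matrix")
    blood = matrix.loc[blood_sample]
    spleen = matrix.loc[spleen_sample]
    target = matrix.loc[target_sample]

    ref_clones = matrix.columns[(blood > 0) | (spleen > 0)]
    if len(ref_clones) < 3:
        raise ValueError("need >= 3 clones detected in blood or spleen")
    d = np.log2((spleen[ref_clones] + floor) / (blood[ref_clones] + floor))
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate reference: blood and spleen ratios have zero spread")
    if empirical_band:
        band_low, band_high = np.quantile(d, [0.005, 0.995])
    else:
        band_low = float(d.mean() - z * sd)
        band_high = float(d.mean() + z * sd)

    call_clones = matrix.columns[(blood > 0) | (target > 0)]
    ratios = np.log2((target[call_clones] + floor) / (blood[call_clones] + floor))
    calls = np.where(ratios > band_high, "tissue_biased",
                     np.where(ratios < band_low, "blood_biased", "unbiased"))
    return pd.DataFrame({
        "clone": call_clones,
        "tissue": target_sample,
        "log2_ratio": ratios.to_numpy(),
        "band_low": band_low,
        "band_high": band_high,
        "call": calls,
    }).reset_index(drop=True)


def classify_trajectories(trajectories: pd.DataFrame, k: int = 2, seed: int = 0,
                          floor: float = ABUNDANCE_FLOOR) -> pd.DataFrame:
    """Split clones into expanding vs diminishing serial-transplant classes.

    ``trajectories`` is clones x passages of mean abundance (%) across mice.
    Features are log10(abundance + floor) per passage (abundances span orders
    of magnitude).  K-means with k=2 and a fixed seed clusters the clones;
    the cluster whose centroid gains more from first to last passage is
    labelled "expanding", the other "diminishing".
    """
    if trajectories.shape[0] < k:
        raise ValueError(f"need at least {k} clones for k={k} clustering")
    if trajectories.shape[1] < 2:
        raise ValueError("need at least 2 passages")
    feats = np.log10(trajectories.to_numpy(float) + floor)
    if np.allclose(feats, feats[0]):
        warnings.warn("all trajectories identical; single-cluster degenerate case",
                      stacklevel=2)
        trend = feats[0, -1] - feats[0, 0]
        label = "expanding" if trend > 0 else "diminishing"
        return pd.DataFrame({"clone": trajectories.index, "class": label})
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(feats)
    trend = km.cluster_centers_[:, -1] - km.cluster_centers_[:, 0]
    expanding_cluster = int(np.argmax(trend))
    labels = np.where(km.labels_ == expanding_cluster, "expanding", "diminishing")
    return pd.DataFrame({"clone": trajectories.index, "class": labels})


def treatment_log2fc(matrix: pd.DataFrame, clone: str,
                     samples_a: Sequence[str], samples_b: Sequence[str],
                     floor: float = ABUNDANCE_FLOOR) -> float:
    """log2 fold difference of a clone's mean abundance between two treatments.

    Means are taken over mice within a tissue; the floor keeps the ratio
    finite (and cancels when both means are 0, giving 0).
    """
    if not list(samples_a) or not list(samples_b):
        raise ValueError("both treatment sample sets must be non-empty")
    mean_a = float(matrix.loc[list(samples_a), clone].mean())
    mean_b = float(matrix.loc[list(samples_b), clone].mean())
    return float(np.log2((mean_a + floor) / (mean_b + floor)))


def clone_response_test(arm_abundances: Mapping[str, Mapping[str, Sequence[float]]]
                        ) -> pd.DataFrame:
    """Per-clone Kruskal-Wallis test of abundance across treatment arms.

    ``arm_abundances`` maps clone -> arm -> abundance observations (one per
    mouse).  Arms with fewer than 2 observations are dropped; clones left
    with fewer than 2 arms are skipped with a warning.  Two-sided p-values
    are Bonferroni-corrected by the number of clones tested (capped at 1).
    """
    rows = []
    skipped = []
    for clone in sorted(arm_abundances):
        arms = {a: np.asarray(v, float) for a, v in arm_abundances[clone].items()
                if len(v) >= 2}
        if len(arms) < 2:
            skipped.append(clone)
            continue
        groups = [arms[a] for a in sorted(arms)]
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:  # scipy.kruskal raises on all-identical input
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append({"clone": clone, "h_statistic": float(h), "p": float(p)})
    if skipped:
        warnings.warn(f"skipped clones with <2 arms of >=2 observations: {skipped}",
                      stacklevel=2)
    out = pd.DataFrame(rows, columns=["clone", "h_statistic", "p"])
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    return out
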