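"""Time-course differential expression of trackable TE loci and genes.

Raw counts are normalised by median-of-ratios size factors, log2
fold-changes computed per timepoint for a declared contrast, significance
assessed by an unequal-variance test on log-normalised counts with
Benjamini-Hochberg adjustment across features. A feature is differentially
expressed when some timepoint has adjusted p below the threshold and
|log2FC| above the effect-size gate. Fold-change profiles of DE features
are clustered hierarchically (Ward/Euclidean) and co-localised DETE-DEG
pairs are scored concordant when they fall in the same joint cluster.

An external DE table (feature, timepoint, lfc, padj) can be supplied in
place of the built-in test so that a negative-binomial engine's output can
drive the identical downstream logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, DEFAULT_CONFIG
from .locus_characterization import CompartmentAssignment

TIMEPOINTS = ("1h", "3h", "6h", "12h")


@dataclass
class DEResult:
    feature_id: str
    log2fc: dict[str, float]
    padj: dict[str, float]
    is_de: bool
    direction: str  # up | down | mixed | none


@dataclass
class ConcordancePair:
    dete_id: str
    deg_id: str
    relationship: str  # exon | intron | N-flank | C-flank
    dete_cluster: int
    deg_cluster: int
    concordant: bool


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over all-nonzero features of
    count / geometric-mean-across-samples.
    """
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "add a pseudocount or filter samples"
        )
    ref = counts.loc[nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref).sub(log_geo_mean, axis=0), axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


def log2fc(
    norm_counts: pd.DataFrame,
    treatment_samples: Sequence[str],
    baseline_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature log2((mean_trt + pc) / (mean_base + pc)) on the normalised scale."""
    trt = norm_counts[list(treatment_samples)].mean(axis=1)
    base = norm_counts[list(baseline_samples)].mean(axis=1)
    return np.log2((trt + pseudocount) / (base + pseudocount))


def de_test(
    norm_counts: pd.DataFrame,
    treatment_samples: Sequence[str],
    baseline_samples: Sequence[str],
    prior_df: float = 10.0,
) -> pd.Series:
    """Moderated two-sample test on log2(norm+1) counts, BH-adjusted.

    Per-feature pooled variances are shrunk toward the across-feature mean
    variance with ``prior_df`` prior degrees of freedom (empirical-Bayes
    moderation in the limma style) — with few replicates per group the
    unmoderated test has almost no power, while variances of log counts
    are highly exchangeable across features.
    """
    if len(treatment_samples) < 2 or len(baseline_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    log_trt = np.log2(norm_counts[list(treatment_samples)].to_numpy() + 1.0)
    log_base = np.log2(norm_counts[list(baseline_samples)].to_numpy() + 1.0)
    n1, n2 = log_trt.shape[1], log_base.shape[1]
    m1, m2 = log_trt.mean(axis=1), log_base.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (log_trt.var(axis=1, ddof=1) * (n1 - 1) + log_base.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid + prior_df)
    p = np.where(np.isnan(p), 1.0, p)
    _rej, padj, _a, _b = multipletests(p, method="fdr_bh")
    return pd.Series(padj, index=norm_counts.index, name="padj")


def run_timecourse_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    treatment: str,
    baseline: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[DEResult]:
    """DE results for a (treatment, baseline) condition contrast over all timepoints.

    ``design`` has columns sample, condition, timepoint, replicate. The
    baseline condition may be sampled at a single timepoint (e.g. an
    untreated time zero), in which case all its samples serve as baseline
    at every timepoint.
    """
    norm = normalize_counts(counts)
    lfc_by_tp: dict[str, pd.Series] = {}
    padj_by_tp: dict[str, pd.Series] = {}
    base_all = design[design["condition"] == baseline]
    for tp in TIMEPOINTS:
        trt = design[(design["condition"] == treatment) & (design["timepoint"] == tp)]["sample"]
        base = base_all[base_all["timepoint"] == tp]["sample"]
        if base.empty:
            base = base_all["sample"]
        lfc_by_tp[tp] = log2fc(norm, list(trt), list(base), config.de_pseudocount)
        padj_by_tp[tp] = de_test(norm, list(trt), list(base))
    return call_de(lfc_by_tp, padj_by_tp, config)


def call_de(
    lfc_by_tp: Mapping[str, pd.Series],
    padj_by_tp: Mapping[str, pd.Series],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[DEResult]:
    """Apply the DE thresholds: padj < de_padj and |lfc| > de_lfc at >=1 timepoint."""
    features = next(iter(lfc_by_tp.values())).index
    results = []
    for fid in features:
        lfc = {tp: float(lfc_by_tp[tp][fid]) for tp in lfc_by_tp}
        padj = {tp: float(padj_by_tp[tp][fid]) for tp in padj_by_tp}
        hits = []
        for tp in lfc:
            effect = abs(lfc[tp]) if config.de_two_sided else lfc[tp]
            if padj[tp] < config.de_padj and effect > config.de_lfc:
                hits.append(np.sign(lfc[tp]))
        if not hits:
            direction = "none"
        elif all(h > 0 for h in hits):
            direction = "up"
        elif all(h < 0 for h in hits):
            direction = "down"
        else:
            direction = "mixed"
        results.append(DEResult(feature_id=fid, log2fc=lfc, padj=padj,
                                is_de=bool(hits), direction=direction))
    return results


def read_external_de(path_or_df) -> tuple[dict[str, pd.Series], dict[str, pd.Series]]:
    """Input port for externally produced DE tables.

    Long format with columns feature, timepoint, lfc, padj; returns the
    (lfc_by_tp, padj_by_tp) pair consumed by :func:`call_de`.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    lfc_by_tp, padj_by_tp = {}, {}
    for tp, sub in df.groupby("timepoint"):
        sub = sub.set_index("feature")
        lfc_by_tp[str(tp)] = sub["lfc"].astype(float)
        padj_by_tp[str(tp)] = sub["padj"].astype(float)
    return lfc_by_tp, padj_by_tp


# ---------------------------------------------------------------------------
# Pattern clustering and DETE-DEG concordance
# ---------------------------------------------------------------------------

def lfc_matrix(results: Sequence[DEResult], only_de: bool = True) -> pd.DataFrame:
    rows = {
        r.feature_id: [r.log2fc[tp] for tp in TIMEPOINTS]
        for r in results
        if r.is_de or not only_de
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TIMEPOINTS))


def name_pattern(profile: Sequence[float], lfc_gate: float = 1.0) -> str:
    """Descriptive name for a mean fold-change profile.

    "up-back"/"down-back": a strong early response (|lfc| > gate by 3 h)
    returning near baseline by 12 h; "up"/"down": sustained response;
    "flat" otherwise.
    """
    profile = np.asarray(profile, dtype=float)
    early = profile[:2].max()
    early_min = profile[:2].min()
    final = profile[-1]
    if early > lfc_gate and abs(final) < lfc_gate:
        return "up-back"
    if early_min < -lfc_gate and abs(final) < lfc_gate:
        return "down-back"
    if profile.max() > lfc_gate and profile.min() > -lfc_gate:
        return "up"
    if profile.min() < -lfc_gate and profile.max() < lfc_gate:
        return "down"
    if abs(profile).max() <= lfc_gate:
        return "flat"
    return "mixed"


def cluster_patterns(
    lfc: pd.DataFrame,
    k: Optional[int] = None,
) -> tuple[pd.Series, dict[int, str]]:
    """Ward hierarchical clustering of fold-change profiles.

    Cuts the tree at ``k`` clusters; when ``k`` is None it is chosen by
    maximum silhouette over k in 2..8. Returns per-feature labels and a
    cluster -> pattern-name map.
    """
    if len(lfc) < 2:
        raise ValueError("need at least two features to cluster")
    X = lfc.to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    if k is None:
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(8, len(lfc) - 1) + 1):
            labels = fcluster(Z, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(X, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    if k > len(lfc):
        raise ValueError(f"k={k} exceeds number of features {len(lfc)}")
    labels = pd.Series(fcluster(Z, k, criterion="maxclust"), index=lfc.index, name="cluster")
    names = {
        int(c): name_pattern(X[labels.to_numpy() == c].mean(axis=0))
        for c in np.unique(labels)
    }
    return labels, names


def pair_and_concordance(
    dete_ids: Sequence[str],
    deg_ids: Sequence[str],
    assignments: Sequence[CompartmentAssignment],
    cluster_labels: pd.Series,
) -> tuple[list[ConcordancePair], float]:
    """Enumerate DETE-DEG pairs and their pattern concordance.

    A pair exists for every DETE assigned to a DEG's gene unit or flanks
    (one row per pair; a DETE co-localised with several DEGs yields several
    pairs). ``cluster_labels`` must come from a joint clustering of the
    pooled DETE+DEG fold-change profiles. Returns the pairs and the
    concordant fraction (nan when no pairs exist).
    """
    deg_set = set(deg_ids)
    dete_set = set(dete_ids)
    by_locus: dict[str, list[CompartmentAssignment]] = {}
    for a in assignments:
        by_locus.setdefault(a.locus_id, []).append(a)
    pairs = []
    for dete in dete_ids:
        for a in by_locus.get(dete, []):
            if a.gene_id in deg_set and dete in dete_set:
                if dete not in cluster_labels.index or a.gene_id not in cluster_labels.index:
                    continue
                c_te = int(cluster_labels[dete])
                c_g = int(cluster_labels[a.gene_id])
                pairs.append(
                    ConcordancePair(
                        dete_id=dete, deg_id=a.gene_id, relationship=a.location,
                        dete_cluster=c_te, deg_cluster=c_g, concordant=c_te == c_g,
                    )
                )
    fraction = (
        sum(p.concordant for p in pairs) / len(pairs) if pairs else float("nan")
    )
    return pairs, fraction
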