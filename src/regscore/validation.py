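"""Validation statistics for the regulatory evidence score.

Three evaluation procedures, each operating on a score map (rsID -> 0-10)
joined against external variant lists:

1. **GWAS binning** — bin SNPs by association -log10 p-value, take the
   mean score per bin, and correlate mean score with bin rank.  A
   MAF-matched background sampler supports the overlay comparison.
2. **MPRA enrichment** — per-score-bin rate of expression-modulating
   variants (emVars) per 1000 reference SNPs, with a paired t-test over
   score bins and a Mann-Whitney U on raw per-variant scores.
3. **Credible sets** — two-sample comparison of scores in fine-mapping
   95% credible sets versus reported top SNPs.

Variants that fail to join to the score map are dropped and counted in
join diagnostics, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GwasRecord",
    "ScoreBinSummary",
    "EnrichmentResult",
    "read_gwas",
    "read_rsid_list",
    "bin_by_significance",
    "score_significance_correlation",
    "match_background",
    "emvar_enrichment",
    "credible_set_comparison",
]

P_FLOOR = 1e-300


class ValidationError(ValueError):
    """Join failures, insufficient data, or degenerate statistics."""


@dataclass(frozen=True)
class GwasRecord:
    """One summary-statistic row: rsID, association p-value, optional MAF."""

    rsid: str
    pvalue: float
    maf: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(
                f"{self.rsid}: p-value must lie in (0, 1], got {self.pvalue}"
            )
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValidationError(
                f"{self.rsid}: maf must lie in (0, 0.5], got {self.maf}"
            )

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.pvalue)


@dataclass
class ScoreBinSummary:
    """Mean score for one significance bin."""

    label: str
    bin_index: int
    n_snps: int
    mean_score: float
    background_mean_score: float | None = None


@dataclass
class EnrichmentResult:
    """Per-score-bin set membership rates plus test statistics.

    ``per_bin`` maps score (0..10) to (n_in_set, n_in_reference,
    rate_per_1000); bins with an empty reference are omitted.
    """

    per_bin: dict[int, tuple[int, int, float]]
    statistic: float
    pvalue: float
    method: str
    secondary_statistic: float | None = None
    secondary_pvalue: float | None = None
    secondary_method: str | None = None


# ---------------------------------------------------------------------------
# input readers


def read_gwas(path: str | Path, p_floor: float = P_FLOOR) -> list[GwasRecord]:
    """Read a headered TSV (rsid, pvalue[, maf]); gzip allowed.

    Zero p-values are clamped up to ``p_floor`` (default 1e-300) with a
    logged count; negative p-values are an error.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in ("rsid", "pvalue") if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    has_maf = "maf" in df.columns
    out: list[GwasRecord] = []
    n_floored = 0
    for row in df.itertuples(index=False):
        p = float(row.pvalue)
        if p < 0:
            raise ValidationError(f"{path}: negative p-value for {row.rsid}")
        if p < p_floor:
            p = p_floor
            n_floored += 1
        maf = float(row.maf) if has_maf and not pd.isna(row.maf) else None
        out.append(GwasRecord(rsid=str(row.rsid), pvalue=p, maf=maf))
    if n_floored:
        logger.info("%s: clamped %d p-value(s) below %g", path, n_floored, p_floor)
    return out


def read_rsid_list(path: str | Path) -> list[str]:
    """Read rsIDs: one per line, or a headered TSV with an ``rsid`` column."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first or first.strip().lower().startswith("rsid"):
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        if "rsid" not in df.columns:
            raise ValidationError(f"{path}: no 'rsid' column in {list(df.columns)}")
        return [str(r) for r in df["rsid"]]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _join_scores(
    rsids: Iterable[str], scores: Mapping[str, int], what: str
) -> tuple[list[str], dict[str, int]]:
    rsids = list(rsids)
    joined = [r for r in rsids if r in scores]
    diag = {"n_input": len(rsids), "n_matched": len(joined)}
    logger.info("%s join: %d of %d matched a score", what, len(joined), len(rsids))
    return joined, diag


# ---------------------------------------------------------------------------
# GWAS binning and correlation


def bin_by_significance(
    records: Sequence[GwasRecord],
    scores: Mapping[str, int],
    *,
    mode: str = "interval",
    min_occupancy: int = 10,
) -> list[ScoreBinSummary]:
    """Mean score per -log10 p bin.

    ``mode="interval"`` uses unit-width bins [t, t+1) on -log10 p;
    ``mode="cumulative"`` uses nested threshold sets p < 10^-t (so bin
    counts overlap and do not sum to n; labels say so).  Bins holding
    fewer than ``min_occupancy`` SNPs are suppressed with a log note.
    """
    if mode not in ("interval", "cumulative"):
        raise ValueError(f"unknown binning mode {mode!r}")
    joined = [(r, scores[r.rsid]) for r in records if r.rsid in scores]
    if not joined:
        raise ValidationError(
            f"no GWAS record joined to a score (n input={len(records)}, n matched=0)"
        )
    logger.info("gwas join: %d of %d matched a score", len(joined), len(records))

    nlp = np.array([r.neglog10p for r, _ in joined])
    sc = np.array([s for _, s in joined], dtype=float)
    max_bin = int(np.floor(nlp.max()))
    out: list[ScoreBinSummary] = []
    for t in range(0, max_bin + 1):
        if mode == "interval":
            mask = (nlp >= t) & (nlp < t + 1)
            label = f"-log10 p in [{t}, {t + 1})"
        else:
            mask = nlp >= t
            label = f"p < 1e-{t} (cumulative)"
        n = int(mask.sum())
        if n == 0:
            continue
        if n < min_occupancy:
            logger.info("suppressing bin %r with %d < %d SNPs", label, n, min_occupancy)
            continue
        out.append(
            ScoreBinSummary(
                label=label, bin_index=t, n_snps=n, mean_score=float(sc[mask].mean())
            )
        )
    return out


def score_significance_correlation(
    bins: Sequence[ScoreBinSummary], method: str = "pearson"
) -> float:
    """Correlation between bin rank (ascending significance) and mean score."""
    if len(bins) < 3:
        raise ValidationError(
            f"insufficient bins for correlation: {len(bins)} < 3"
        )
    ranks = np.arange(len(bins), dtype=float)
    means = np.array([b.mean_score for b in bins])
    if np.allclose(means, means[0]):
        raise ValidationError(
            "correlation undefined: mean score is constant across bins"
        )
    if method == "pearson":
        r = stats.pearsonr(ranks, means).statistic
    elif method == "spearman":
        r = stats.spearmanr(ranks, means).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


# ---------------------------------------------------------------------------
# MAF-matched background


def match_background(
    target: Sequence[GwasRecord],
    universe: Sequence[GwasRecord],
    *,
    maf_bin_width: float = 0.05,
    seed: int = 0,
) -> list[GwasRecord]:
    """One MAF-matched universe SNP per target SNP, without replacement.

    MAF bins are [k*w, (k+1)*w).  Universe records sharing an rsID with a
    target are excluded.  Targets whose bin is exhausted (or lack a MAF)
    are skipped with a logged count.  Reproducible under a fixed seed.
    """
    if not universe:
        raise ValidationError("background universe is empty")
    rng = np.random.default_rng(seed)
    target_ids = {t.rsid for t in target}

    def maf_bin(maf: float) -> int:
        return int(maf // maf_bin_width)

    pools: dict[int, list[GwasRecord]] = {}
    for u in universe:
        if u.rsid in target_ids or u.maf is None:
            continue
        pools.setdefault(maf_bin(u.maf), []).append(u)
    # deterministic pool order, then seeded shuffle -> pop draws uniformly
    for b, pool in pools.items():
        pool.sort(key=lambda r: r.rsid)
        rng.shuffle(pool)

    matched: list[GwasRecord] = []
    n_skipped = 0
    for t in target:
        if t.maf is None:
            n_skipped += 1
            continue
        pool = pools.get(maf_bin(t.maf))
        if not pool:
            n_skipped += 1
            continue
        matched.append(pool.pop())
    if n_skipped:
        logger.info("background matching skipped %d target(s)", n_skipped)
    return matched


# ---------------------------------------------------------------------------
# MPRA emVar enrichment


def emvar_enrichment(
    emvars: Iterable[str],
    reference: Iterable[str],
    scores: Mapping[str, int],
    *,
    max_score: int = 10,
) -> EnrichmentResult:
    """Per-score-bin emVar rate per 1000 reference SNPs, with two tests.

    Primary test: paired t-test across score bins, pairing the emVar and
    reference score-distribution proportions weighted by score
    (``s * p_set[s]`` vs ``s * p_ref[s]``), so the mean paired difference
    equals the mean-score difference between the sets.  Secondary test:
    Mann-Whitney U on raw per-variant scores — assumption-light, reported
    because bin-level pairing has few degrees of freedom.

    Reference bins with zero variants are omitted from ``per_bin`` and
    from the paired test.
    """
    em_joined, em_diag = _join_scores(emvars, scores, "emvar")
    ref_joined, ref_diag = _join_scores(reference, scores, "reference")
    if not em_joined:
        raise ValidationError(
            f"no emVar joined to a score "
            f"(n input={em_diag['n_input']}, n matched=0)"
        )
    if not ref_joined:
        raise ValidationError(
            f"no reference variant joined to a score "
            f"(n input={ref_diag['n_input']}, n matched=0)"
        )

    em_scores = np.array([scores[r] for r in em_joined], dtype=float)
    ref_scores = np.array([scores[r] for r in ref_joined], dtype=float)
    em_counts = np.bincount(em_scores.astype(int), minlength=max_score + 1)
    ref_counts = np.bincount(ref_scores.astype(int), minlength=max_score + 1)

    per_bin: dict[int, tuple[int, int, float]] = {}
    for s in range(max_score + 1):
        if ref_counts[s] == 0:
            continue
        per_bin[s] = (
            int(em_counts[s]),
            int(ref_counts[s]),
            1000.0 * em_counts[s] / ref_counts[s],
        )

    populated = np.array(sorted(per_bin), dtype=int)
    em_prop = em_counts[populated] / em_counts.sum()
    ref_prop = ref_counts[populated] / ref_counts.sum()
    t_res = stats.ttest_rel(populated * em_prop, populated * ref_prop)
    mw = stats.mannwhitneyu(em_scores, ref_scores, alternative="two-sided")

    return EnrichmentResult(
        per_bin=per_bin,
        statistic=float(t_res.statistic),
        pvalue=float(t_res.pvalue),
        method="paired t-test on score-weighted bin proportions",
        secondary_statistic=float(mw.statistic),
        secondary_pvalue=float(mw.pvalue),
        secondary_method="Mann-Whitney U on per-variant scores",
    )


# ---------------------------------------------------------------------------
# credible sets


def credible_set_comparison(
    credible_scores: Sequence[float],
    top_snp_scores: Sequence[float],
    *,
    method: str = "welch",
) -> tuple[float, float, str]:
    """Compare mean scores of credible-set variants vs reported top SNPs.

    Returns (statistic, p-value, direction), direction being "higher",
    "lower" or "equal" for the credible set relative to the top SNPs.
    Welch's t-test by default; ``method="mannwhitney"`` for the rank test.
    """
    if len(credible_scores) < 2 or len(top_snp_scores) < 2:
        raise ValidationError(
            "need >= 2 scores on each side, got "
            f"{len(credible_scores)} and {len(top_snp_scores)}"
        )
    a = np.asarray(credible_scores, dtype=float)
    b = np.asarray(top_snp_scores, dtype=float)
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = a.mean() - b.mean()
    direction = "higher" if diff > 0 else ("lower" if diff < 0 else "equal")
    return float(res.statistic), float(res.pvalue), direction
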