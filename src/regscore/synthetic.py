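"""Seeded synthetic fixtures with planted ground truth.

Generates everything the annotation and validation pipelines consume —
variant lists, regional tracks, keyed evidence tables, GWAS summary
statistics, MPRA emVar/tested sets — on a small pseudo-genome, with the
true evidence-flag matrix (and hence the true score of every variant)
recorded alongside.  This makes every pipeline stage testable end-to-end
with no external downloads.

Planting is exact, not probabilistic: for a variant whose flag is true in
a category, an interval of that category strictly covers its position; for
a false flag, no interval of that category does.  Decoy intervals (placed
with >= 1 bp clearance from every variant) keep the tracks from being
trivially variant-shaped.  Variants are laid out on a slot grid whose
pitch exceeds twice the maximum interval length, so a planted interval
can never accidentally reach a neighbouring variant.

All randomness flows from one integer seed through
``numpy.random.SeedSequence(seed).spawn``: child streams are drawn in a
fixed order (layout, alleles, per-category intervals, tables, decoys), so
every emitted file is byte-reproducible independently of the others.

The generator emulates planted presence/absence and a tunable
score-significance dependence only; it makes no attempt to mimic real LD
structure, real MAF spectra, or real track density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evidence import SCORED_CATEGORIES, Variant
from .intervals import GenomicInterval, write_bed
from .scoring import DEFAULT_SCHEME, ScoreScheme
from .validation import GwasRecord

__all__ = [
    "FixtureParams",
    "FixtureTruth",
    "GwasModel",
    "generate_fixtures",
    "generate_gwas",
    "generate_mpra_sets",
]

_BASES = np.array(list("ACGT"))
_MAX_PLACEMENT_ATTEMPTS = 100


@dataclass(frozen=True)
class FixtureParams:
    """Generation parameters; defaults define the reference study conditions.

    ``presence_probs`` gives the independent per-category probability that
    a variant carries each evidence line; ``interval_len`` bounds planted
    interval lengths (bp, a plausible hotspot/peak scale); the pseudo-
    genome is 3 chromosomes of 10 Mb.
    """

    n_variants: int = 2000
    presence_probs: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in SCORED_CATEGORIES}
    )
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000
        }
    )
    seed: int = 7
    interval_len: tuple[int, int] = (150, 2000)
    decoy_prob: float = 0.5
    report_table_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        for cat, p in self.presence_probs.items():
            if cat not in SCORED_CATEGORIES:
                raise ValueError(f"unknown category {cat!r} in presence_probs")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"presence prob for {cat} outside [0, 1]: {p}")
        if not self.chrom_sizes:
            raise ValueError("need >= 1 chromosome")
        for chrom, size in self.chrom_sizes.items():
            if size < 10_000:
                raise ValueError(f"{chrom}: chromosome size must be >= 10 kb")

    @property
    def slot_width(self) -> int:
        # pitch > 2 * max interval length + jitter, so planted intervals
        # cannot reach a neighbouring slot's variant
        return 3 * self.interval_len[1]

    def prob_vector(self) -> np.ndarray:
        return np.array([self.presence_probs.get(c, 0.0) for c in SCORED_CATEGORIES])


@dataclass
class FixtureTruth:
    """Planted ground truth for one generated fixture set."""

    params: FixtureParams
    variants: list[Variant]
    flags: dict[str, tuple[bool, ...]]  # rsid -> flag sextet, category order
    scores: dict[str, int]              # rsid -> planted scheme-sum
    files: dict[str, Path]

    def flag_matrix(self) -> np.ndarray:
        return np.array([self.flags[v.rsid] for v in self.variants], dtype=bool)

    def score_vector(self) -> np.ndarray:
        return np.array([self.scores[v.rsid] for v in self.variants], dtype=int)


def _spawn_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _layout_variants(
    params: FixtureParams, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """(chrom, 1-based pos) per variant, on a slot grid, shuffled order."""
    w = params.slot_width
    slots: list[tuple[str, int]] = []
    for chrom in params.chrom_sizes:  # insertion order: deterministic
        n_slots = params.chrom_sizes[chrom] // w
        slots.extend((chrom, i) for i in range(n_slots))
    if params.n_variants > len(slots):
        raise ValueError(
            f"cannot place {params.n_variants} variants in {len(slots)} slots; "
            "enlarge the chromosomes or reduce n_variants"
        )
    idx = rng.choice(len(slots), size=params.n_variants, replace=False)
    idx.sort()
    out = []
    l_max = params.interval_len[1]
    for i in idx:
        chrom, slot = slots[i]
        # pos0 sits >= l_max into the slot and >= l_max before its end
        jitter = int(rng.integers(0, w - 2 * l_max - 1))
        pos0 = slot * w + l_max + jitter
        out.append((chrom, pos0 + 1))
    return out


def _plant_interval(
    chrom: str,
    pos0: int,
    forbidden: set[tuple[str, int]],
    rng: np.random.Generator,
    lo: int,
    hi: int,
    label: str,
) -> GenomicInterval:
    """An interval covering pos0 but no forbidden (chrom, pos0) point."""
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        length = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, length))
        start = max(0, pos0 - offset)
        end = start + length
        covered = {
            (chrom, p) for (c, p) in forbidden if c == chrom and start <= p < end
        }
        if not covered:
            return GenomicInterval(
                chrom=chrom, start=start, end=end, name=label, source=label
            )
    raise RuntimeError(
        f"could not place an interval covering {chrom}:{pos0} without "
        f"violating a planted-absent position after {_MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def generate_fixtures(
    params: FixtureParams = FixtureParams(),
    out_dir: str | Path = "fixtures",
    scheme: ScoreScheme = DEFAULT_SCHEME,
) -> FixtureTruth:
    """Write a complete fixture directory and return its planted truth.

    Emits ``variants.tsv``; one regional track per scored category
    (``dnase.bed``, ``histone.broadPeak``, ``tf_motif.bed``, ``abc.bed``);
    keyed tables ``cato.tsv`` and ``eqtl.tsv`` holding rows exactly for
    flagged variants; report-only ``cadd.tsv``, ``phylop.tsv`` and
    ``genes.bed`` for a random subset; and ``truth.tsv`` with the planted
    flag sextet and score per variant.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rngs = _spawn_rngs(
        params.seed,
        ["layout", "alleles", "flags", "intervals", "decoys", "tables", "genes"],
    )

    positions = _layout_variants(params, rngs["layout"])
    n = params.n_variants
    ref_idx = rngs["alleles"].integers(0, 4, size=n)
    alt_off = rngs["alleles"].integers(1, 4, size=n)
    mafs = rngs["alleles"].uniform(0.01, 0.5, size=n)
    variants = [
        Variant(
            rsid=f"rs{9_000_000 + i}",
            chrom=chrom,
            pos=pos,
            ref=str(_BASES[ref_idx[i]]),
            alt=str(_BASES[(ref_idx[i] + alt_off[i]) % 4]),
            maf=round(float(mafs[i]), 4),
        )
        for i, (chrom, pos) in enumerate(positions)
    ]

    flag_matrix = rngs["flags"].random((n, len(SCORED_CATEGORIES))) < params.prob_vector()
    flags = {
        v.rsid: tuple(bool(b) for b in flag_matrix[i]) for i, v in enumerate(variants)
    }
    scores = {
        rsid: sum(
            scheme.points(cat) for cat, on in zip(SCORED_CATEGORIES, fl) if on
        )
        for rsid, fl in flags.items()
    }

    files: dict[str, Path] = {}

    files["variants"] = out_dir / "variants.tsv"
    with open(files["variants"], "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tmaf\n")
        for v in variants:
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.maf}\n")

    lo, hi = params.interval_len
    track_names = {
        "dnase": "dnase.bed",
        "histone": "histone.broadPeak",
        "tf_motif": "tf_motif.bed",
        "abc": "abc.bed",
    }
    regional = ("dnase", "histone", "tf_motif", "abc")
    for ci, cat in enumerate(regional):
        cat_i = SCORED_CATEGORIES.index(cat)
        absent = {
            (v.chrom, v.pos0) for i, v in enumerate(variants) if not flag_matrix[i, cat_i]
        }
        intervals: list[GenomicInterval] = []
        for i, v in enumerate(variants):
            if flag_matrix[i, cat_i]:
                intervals.append(
                    _plant_interval(
                        v.chrom, v.pos0, absent, rngs["intervals"], lo, hi,
                        f"{cat}_region",
                    )
                )
        # decoys live in the slot's leading margin, clear of every variant
        w = params.slot_width
        for i, v in enumerate(variants):
            if flag_matrix[i, cat_i] or rngs["decoys"].random() >= params.decoy_prob:
                continue
            slot_start = (v.pos0 // w) * w
            length = int(rngs["decoys"].integers(50, lo + 1))
            start = slot_start + int(rngs["decoys"].integers(0, lo - length + 1))
            decoy = GenomicInterval(
                chrom=v.chrom, start=start, end=start + length,
                name=f"{cat}_decoy", source=f"{cat}_decoy",
            )
            # decoy safety: margin ends >= interval_len[1] before any pos0
            assert not any(
                decoy.start <= u.pos0 < decoy.end
                for u in variants if u.chrom == decoy.chrom
            )
            intervals.append(decoy)
        intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        if cat == "histone":
            # broadPeak payload: score, strand, signal, p, q columns
            intervals = [
                GenomicInterval(
                    chrom=iv.chrom, start=iv.start, end=iv.end, name=iv.name,
                    source=iv.source,
                    extra=("0", ".", "1.0", "-1", "-1"),
                )
                for iv in intervals
            ]
        files[cat] = out_dir / track_names[cat]
        write_bed(intervals, files[cat])

    rng_t = rngs["tables"]
    files["cato"] = out_dir / "cato.tsv"
    cato_i = SCORED_CATEGORIES.index("cato")
    with open(files["cato"], "w") as fh:
        fh.write("rsid\tallele\tscore\n")
        for i, v in enumerate(variants):
            if flag_matrix[i, cato_i]:
                fh.write(f"{v.rsid}\t{v.alt}\t{round(float(rng_t.uniform(0.1, 1.0)), 4)}\n")

    files["eqtl"] = out_dir / "eqtl.tsv"
    eqtl_i = SCORED_CATEGORIES.index("eqtl")
    with open(files["eqtl"], "w") as fh:
        fh.write("rsid\tsource\tgene\teffect_allele\tstatistic\n")
        for i, v in enumerate(variants):
            if not flag_matrix[i, eqtl_i]:
                continue
            stat = round(float(rng_t.uniform(5, 50)), 3)
            fh.write(f"{v.rsid}\tgtex\tGENE_{v.chrom}_{v.pos // 500_000}\t{v.alt}\t{stat}\n")
            if rng_t.random() < 0.5:  # second, blood-eQTL-style source
                stat2 = round(float(rng_t.uniform(5, 50)), 3)
                fh.write(
                    f"{v.rsid}\teqtlgen\tGENE_{v.chrom}_{v.pos // 500_000}\t{v.alt}\t{stat2}\n"
                )

    for name, col in (("cadd", "score"), ("phylop", "score")):
        files[name] = out_dir / f"{name}.tsv"
        with open(files[name], "w") as fh:
            fh.write(f"rsid\t{col}\n")
            for v in variants:
                if rng_t.random() < params.report_table_prob:
                    val = round(float(rng_t.uniform(-2, 30)), 3)
                    fh.write(f"{v.rsid}\t{val}\n")

    files["genes"] = out_dir / "genes.bed"
    gene_ivs = []
    for chrom, size in params.chrom_sizes.items():
        for k, gstart in enumerate(range(100_000, size - 100_000, 500_000)):
            glen = int(rngs["genes"].integers(20_000, 80_000))
            gene_ivs.append(
                GenomicInterval(
                    chrom=chrom, start=gstart, end=gstart + glen,
                    name=f"GENE_{chrom}_{k}", source="genes",
                )
            )
    write_bed(gene_ivs, files["genes"])

    files["truth"] = out_dir / "truth.tsv"
    with open(files["truth"], "w") as fh:
        fh.write("rsid\t" + "\t".join(SCORED_CATEGORIES) + "\tscore\n")
        for v in variants:
            fl = flags[v.rsid]
            fh.write(
                v.rsid + "\t"
                + "\t".join(str(int(b)) for b in fl)
                + f"\t{scores[v.rsid]}\n"
            )

    return FixtureTruth(
        params=params, variants=variants, flags=flags, scores=scores, files=files
    )


@dataclass(frozen=True)
class GwasModel:
    """Planted score-significance dependence:
    -log10 p = a + b * score + Normal(0, sigma), truncated at 0 (p <= 1).

    ``b = 0`` is the null GWAS (significance independent of score).
    """

    a: float = 1.0
    b: float = 0.5
    sigma: float = 0.5

    @classmethod
    def null(cls, sigma: float = 1.0) -> "GwasModel":
        return cls(a=1.0, b=0.0, sigma=sigma)


def generate_gwas(
    truth: FixtureTruth,
    model: GwasModel = GwasModel(),
    seed: int = 0,
    out_path: str | Path | None = None,
) -> list[GwasRecord]:
    """One GWAS record per fixture variant under the planted model.

    MAF is re-drawn Uniform(0.01, 0.5) independent of the variant file so
    background matching can be exercised on its own stream.
    """
    rng = np.random.default_rng(seed)
    scores = truth.score_vector().astype(float)
    nlp = model.a + model.b * scores + rng.normal(0.0, model.sigma, size=len(scores))
    nlp = np.clip(nlp, 0.0, 300.0)
    pvals = np.power(10.0, -nlp)
    mafs = rng.uniform(0.01, 0.5, size=len(scores))
    records = [
        GwasRecord(rsid=v.rsid, pvalue=float(p), maf=round(float(m), 4))
        for v, p, m in zip(truth.variants, pvals, mafs)
    ]
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("rsid\tpvalue\tmaf\n")
            for r in records:
                fh.write(f"{r.rsid}\t{r.pvalue:.6g}\t{r.maf}\n")
    return records


def generate_mpra_sets(
    truth: FixtureTruth,
    enrichment_strength: float = 2.0,
    n_emvars: int = 248,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[str], list[str]]:
    """emVar and tested rsID sets with score-dependent emVar sampling.

    emVars are drawn without replacement with probability proportional to
    ``enrichment_strength ** score`` (1.0 gives the uniform null;
    ``math.inf`` takes only the maximal populated score bin).  The tested
    set is the full fixture variant list, a uniform superset.
    """
    if enrichment_strength < 0:
        raise ValueError("enrichment_strength must be >= 0")
    if n_emvars > len(truth.variants):
        raise ValueError("n_emvars exceeds the number of fixture variants")
    rng = np.random.default_rng(seed)
    rsids = np.array([v.rsid for v in truth.variants])
    scores = truth.score_vector().astype(float)

    if math.isinf(enrichment_strength):
        top = scores == scores.max()
        pool = rsids[top]
        take = min(n_emvars, pool.size)
        emvars = list(rng.choice(pool, size=take, replace=False))
    else:
        # Efraimidis-Spirakis weighted sampling without replacement
        logw = scores * math.log(enrichment_strength) if enrichment_strength > 0 else (
            np.where(scores == 0, 0.0, -np.inf)
        )
        keys = np.log(-np.log(rng.random(len(scores)))) - logw
        emvars = list(rsids[np.argsort(keys, kind="stable")[:n_emvars]])

    tested = list(rsids)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "emvars.txt").write_text("\n".join(emvars) + "\n")
        (out_dir / "tested.txt").write_text("\n".join(tested) + "\n")
    return emvars, tested
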