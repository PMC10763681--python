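"""Evidence catalog loading and per-variant annotation resolution.

Two lookup semantics coexist, mirroring how regulatory annotation sources
are distributed:

* **regional** evidence is positional: a variant carries the annotation iff
  its position falls inside at least one interval of that category, across
  the union of all loaded tracks (DNase I hotspots, histone-mark broadPeaks,
  TF motif hits, activity-by-contact enhancer regions; chromatin states,
  sgRNA regions and gene bodies are regional but report-only);
* **variant-level** evidence is allele-specific and keyed by rsID
  (CATO transcription-factor occupancy scores, significant eQTLs from
  GTEx-style and blood-eQTLGen-style tables; CADD and PhyloP are keyed but
  report-only).

Six indicators feed the score: dnase, histone, tf_motif, cato, abc, eqtl.
Everything else is carried through to the report unscored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .intervals import GenomicInterval, IntervalIndex, read_bed

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "CatalogConfig",
    "EvidenceCatalog",
    "EvidenceProfile",
    "read_variants",
    "load_catalog",
    "evaluate",
    "closest_gene",
    "SCORED_CATEGORIES",
    "REGIONAL_SCORED",
]

# the six score-relevant indicators, in canonical order
SCORED_CATEGORIES = ("dnase", "histone", "tf_motif", "cato", "abc", "eqtl")
# the regional (stab-query) subset of the above
REGIONAL_SCORED = ("dnase", "histone", "tf_motif", "abc")
# regional categories carried in the report but never scored
REGIONAL_REPORT = ("chromatin_state", "sgrna", "genes")
# rsID/position-keyed tables carried in the report but never scored
TABLE_REPORT = ("cadd", "phylop")

EQTL_SOURCES = frozenset({"gtex", "eqtlgen"})


class VariantInputError(ValueError):
    """Invalid variant input: missing columns, bad coordinates, conflicts."""


class CatalogError(ValueError):
    """Invalid catalog configuration (unknown category, missing file)."""


@dataclass(frozen=True)
class Variant:
    """A SNP: rsID, 1-based position, one ref/alt allele pair, optional MAF."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise VariantInputError("rsid must be non-empty")
        if self.pos < 1:
            raise VariantInputError(
                f"{self.rsid}: position must be >= 1 (1-based), got {self.pos}"
            )
        if not self.ref or not self.alt:
            raise VariantInputError(f"{self.rsid}: ref and alt must be non-empty")
        if self.ref == self.alt:
            raise VariantInputError(f"{self.rsid}: ref and alt must differ")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise VariantInputError(
                f"{self.rsid}: maf must lie in [0, 0.5], got {self.maf}"
            )

    @property
    def pos0(self) -> int:
        """0-based stab position: the first reference base."""
        return self.pos - 1


@dataclass
class CatalogConfig:
    """Paths per evidence category plus lookup thresholds.

    ``tracks`` maps regional categories to lists of BED/broadPeak paths;
    ``tables`` maps keyed categories to TSV paths.  ``cato_min`` (optional)
    filters CATO records below a score threshold; ``eqtl_min_stat``
    (optional) filters eQTL rows whose ``statistic`` column is below a
    threshold, for tables not pre-filtered to significant eQTLs.
    ``strict_alleles`` demotes allele-mismatched table records from
    presence evidence to report-only detail.
    """

    tracks: dict[str, list[Path]] = field(default_factory=dict)
    tables: dict[str, list[Path]] = field(default_factory=dict)
    cato_min: float | None = None
    eqtl_min_stat: float | None = None
    strict_alleles: bool = False
    normalize_chr: bool = False

    _TRACK_CATEGORIES = set(REGIONAL_SCORED) | set(REGIONAL_REPORT)
    _TABLE_CATEGORIES = {"cato", "eqtl"} | set(TABLE_REPORT)

    @classmethod
    def from_paths(cls, **kwargs: Any) -> "CatalogConfig":
        """Build a config from ``category=path-or-list`` keyword arguments."""
        opts = {
            k: kwargs.pop(k)
            for k in ("cato_min", "eqtl_min_stat", "strict_alleles", "normalize_chr")
            if k in kwargs
        }
        cfg = cls(**opts)
        for category, paths in kwargs.items():
            if paths is None:
                continue
            if isinstance(paths, (str, Path)):
                paths = [paths]
            paths = [Path(p) for p in paths]
            if category in cls._TRACK_CATEGORIES:
                cfg.tracks.setdefault(category, []).extend(paths)
            elif category in cls._TABLE_CATEGORIES:
                cfg.tables.setdefault(category, []).extend(paths)
            else:
                raise CatalogError(f"unknown evidence category: {category!r}")
        return cfg


@dataclass
class EvidenceCatalog:
    """Indexed regional tracks and keyed variant-level tables per category."""

    dnase: IntervalIndex
    histone: IntervalIndex
    tf_motif: IntervalIndex
    abc: IntervalIndex
    chromatin_state: IntervalIndex
    sgrna: IntervalIndex
    genes: IntervalIndex
    cato: dict[str, list[dict[str, Any]]]
    eqtl: dict[str, list[dict[str, Any]]]
    cadd: dict[str, list[dict[str, Any]]]
    phylop: dict[str, list[dict[str, Any]]]
    config: CatalogConfig = field(default_factory=CatalogConfig)

    def index_for(self, category: str) -> IntervalIndex:
        return getattr(self, category)

    @property
    def empty_scored_categories(self) -> list[str]:
        """Scored categories with no data loaded ("data absent", not
        "evidence absent")."""
        out = []
        for cat in REGIONAL_SCORED:
            if len(self.index_for(cat)) == 0:
                out.append(cat)
        if not self.cato:
            out.append("cato")
        if not self.eqtl:
            out.append("eqtl")
        return out

    def manifest(self) -> dict[str, dict[str, int]]:
        """Category -> {files, records}, for run logging."""
        m: dict[str, dict[str, int]] = {}
        for cat in REGIONAL_SCORED + REGIONAL_REPORT:
            idx = self.index_for(cat)
            m[cat] = {
                "files": len(self.config.tracks.get(cat, [])),
                "records": len(idx),
            }
        for cat in ("cato", "eqtl") + TABLE_REPORT:
            table: dict = getattr(self, cat)
            m[cat] = {
                "files": len(self.config.tables.get(cat, [])),
                "records": sum(len(v) for v in table.values()),
            }
        return m


@dataclass
class EvidenceProfile:
    """Presence/absence of the six score indicators plus supporting detail.

    Invariant: each ``has_*`` flag is true iff the corresponding
    ``details`` list is non-empty.
    """

    has_dnase: bool = False
    has_histone: bool = False
    has_tf_motif: bool = False
    has_cato: bool = False
    has_abc: bool = False
    has_eqtl: bool = False
    details: dict[str, list[Any]] = field(
        default_factory=lambda: {c: [] for c in SCORED_CATEGORIES}
    )
    report_only: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_flags(
        cls,
        dnase: bool = False,
        histone: bool = False,
        tf_motif: bool = False,
        cato: bool = False,
        abc: bool = False,
        eqtl: bool = False,
    ) -> "EvidenceProfile":
        """Profile from bare flags; details get a synthetic placeholder per
        true flag so the flag/details invariant holds."""
        flags = dict(
            dnase=dnase, histone=histone, tf_motif=tf_motif,
            cato=cato, abc=abc, eqtl=eqtl,
        )
        details = {c: ([{"asserted": True}] if flags[c] else []) for c in flags}
        return cls(
            has_dnase=dnase, has_histone=histone, has_tf_motif=tf_motif,
            has_cato=cato, has_abc=abc, has_eqtl=eqtl, details=details,
        )

    @property
    def flags(self) -> tuple[bool, ...]:
        """Indicator flags in canonical category order."""
        return (
            self.has_dnase, self.has_histone, self.has_tf_motif,
            self.has_cato, self.has_abc, self.has_eqtl,
        )

    def flag(self, category: str) -> bool:
        return getattr(self, f"has_{category}")

    def check_consistency(self) -> None:
        for cat in SCORED_CATEGORIES:
            if self.flag(cat) != bool(self.details[cat]):
                raise AssertionError(
                    f"profile inconsistency in {cat}: flag={self.flag(cat)} "
                    f"details={len(self.details[cat])}"
                )

    def merged_with(self, other: "EvidenceProfile") -> "EvidenceProfile":
        """Union of evidence across two profiles (alt alleles of one rsID)."""
        details = {
            c: list(self.details[c]) + [
                d for d in other.details[c] if d not in self.details[c]
            ]
            for c in SCORED_CATEGORIES
        }
        report = dict(self.report_only)
        for k, v in other.report_only.items():
            report.setdefault(k, v)
        merged = EvidenceProfile(details=details, report_only=report)
        for cat in SCORED_CATEGORIES:
            setattr(merged, f"has_{cat}", bool(details[cat]))
        return merged


# ---------------------------------------------------------------------------
# variant input


_VARIANT_COLUMNS = ("rsid", "chrom", "pos", "ref", "alt")


def _read_variants_tsv(path: Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    missing = [c for c in _VARIANT_COLUMNS if c not in cols]
    if missing:
        raise VariantInputError(
            f"{path}: missing required column(s) {missing}; found {cols}"
        )
    has_maf = "maf" in cols
    out: list[Variant] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        try:
            pos = int(rec["pos"])
        except (TypeError, ValueError):
            raise VariantInputError(
                f"{path}: non-integer position {rec['pos']!r} for {rec['rsid']}"
            ) from None
        maf = None
        if has_maf and rec.get("maf") not in (None, "", "NA"):
            maf = float(rec["maf"])
        out.append(
            Variant(
                rsid=rec["rsid"], chrom=rec["chrom"], pos=pos,
                ref=rec["ref"], alt=rec["alt"], maf=maf,
            )
        )
    return out


def _read_variants_vcf(path: Path) -> list[Variant]:
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.id is None or rec.id == ".":
                raise VariantInputError(
                    f"{path}: record at {rec.chrom}:{rec.pos} has no ID; "
                    "rsID-keyed lookups require a non-'.' ID column"
                )
            for alt in rec.alts or ():
                out.append(
                    Variant(
                        rsid=rec.id, chrom=rec.chrom, pos=rec.pos,
                        ref=rec.ref, alt=alt,
                    )
                )
    return out


def read_variants(path: str | Path) -> list[Variant]:
    """Read a variant list from headered TSV or VCF.

    TSV columns (case-insensitive): rsid, chrom, pos, ref, alt[, maf].
    VCF: the five mandatory columns are used; the ID must be set.
    Multi-allelic records are split into one :class:`Variant` per alt.
    Exact duplicate rows are dropped (with a logged count); the same rsID
    at conflicting coordinates is an error.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        variants = _read_variants_vcf(path)
    else:
        variants = _read_variants_tsv(path)

    seen: dict[tuple, Variant] = {}
    by_rsid: dict[str, tuple[str, int]] = {}
    deduped: list[Variant] = []
    n_dupes = 0
    for v in variants:
        key = (v.rsid, v.chrom, v.pos, v.ref, v.alt)
        if key in seen:
            n_dupes += 1
            continue
        prev = by_rsid.get(v.rsid)
        if prev is not None and prev != (v.chrom, v.pos):
            raise VariantInputError(
                f"{path}: rsID {v.rsid} appears at conflicting coordinates "
                f"{prev[0]}:{prev[1]} and {v.chrom}:{v.pos}"
            )
        seen[key] = v
        by_rsid[v.rsid] = (v.chrom, v.pos)
        deduped.append(v)
    if n_dupes:
        logger.info("%s: dropped %d exact duplicate row(s)", path, n_dupes)
    return deduped


# ---------------------------------------------------------------------------
# catalog loading


def _load_keyed_table(
    category: str, paths: Sequence[Path]
) -> dict[str, list[dict[str, Any]]]:
    """Load rsID/position-keyed TSVs into key -> row-dicts.

    Keys: the ``rsid`` column when present; otherwise a positional key
    ``chrom:pos[:ref:alt]`` assembled from coordinate columns.
    """
    table: dict[str, list[dict[str, Any]]] = {}
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        if "rsid" in df.columns:
            keyer = lambda rec: rec["rsid"]
        elif {"chrom", "pos"} <= set(df.columns):
            coord_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
            keyer = lambda rec: ":".join(str(rec[c]) for c in coord_cols)
        else:
            raise CatalogError(
                f"{category} table {path}: needs an 'rsid' column or "
                f"'chrom'+'pos' columns; found {list(df.columns)}"
            )
        for row in df.itertuples(index=False):
            rec = dict(row._asdict())
            rec["_source_file"] = path.name
            table.setdefault(keyer(rec), []).append(rec)
    return table


def load_catalog(config: CatalogConfig) -> EvidenceCatalog:
    """Load and index every configured evidence file.

    All tracks of a category are pooled into one index (union semantics).
    A scored category with no files is a warning — every variant then
    scores 0 on it — never an error.  A configured path that does not
    exist is an error naming the category and path.
    """
    for category in config.tracks:
        if category not in CatalogConfig._TRACK_CATEGORIES:
            raise CatalogError(f"unknown track category: {category!r}")
    for category in config.tables:
        if category not in CatalogConfig._TABLE_CATEGORIES:
            raise CatalogError(f"unknown table category: {category!r}")
    for category, paths in list(config.tracks.items()) + list(config.tables.items()):
        for p in paths:
            if not Path(p).exists():
                raise CatalogError(f"{category}: file not found: {p}")

    indexes: dict[str, IntervalIndex] = {}
    for category in REGIONAL_SCORED + REGIONAL_REPORT:
        idx = IntervalIndex()
        for p in config.tracks.get(category, []):
            for iv in read_bed(p, normalize_chr=config.normalize_chr):
                idx.add(iv)
        indexes[category] = idx

    tables: dict[str, dict[str, list[dict[str, Any]]]] = {}
    for category in ("cato", "eqtl") + TABLE_REPORT:
        paths = config.tables.get(category, [])
        tables[category] = _load_keyed_table(category, paths) if paths else {}

    for rows in tables["eqtl"].values():
        for rec in rows:
            src = rec.get("source")
            if src is not None and src not in EQTL_SOURCES:
                raise CatalogError(
                    f"eqtl table: source {src!r} outside vocabulary "
                    f"{sorted(EQTL_SOURCES)}"
                )

    catalog = EvidenceCatalog(
        dnase=indexes["dnase"],
        histone=indexes["histone"],
        tf_motif=indexes["tf_motif"],
        abc=indexes["abc"],
        chromatin_state=indexes["chromatin_state"],
        sgrna=indexes["sgrna"],
        genes=indexes["genes"],
        cato=tables["cato"],
        eqtl=tables["eqtl"],
        cadd=tables["cadd"],
        phylop=tables["phylop"],
        config=config,
    )
    for cat in catalog.empty_scored_categories:
        logger.warning(
            "scored category %r has no data: all variants score 0 on it", cat
        )
    for cat, counts in catalog.manifest().items():
        logger.info(
            "catalog %-16s files=%d records=%d", cat, counts["files"], counts["records"]
        )
    return catalog


# ---------------------------------------------------------------------------
# per-variant evaluation


def _allele_match(variant: Variant, record: Mapping[str, Any]) -> bool | None:
    """True/False if the record names alleles, None if it does not."""
    alleles = {
        str(record[k]).upper()
        for k in ("allele", "effect_allele", "tested_allele", "ref", "alt")
        if record.get(k) not in (None, "", "NA")
    }
    if not alleles:
        return None
    return variant.ref.upper() in alleles or variant.alt.upper() in alleles


def _table_lookup(
    variant: Variant,
    table: dict[str, list[dict[str, Any]]],
    *,
    min_score: float | None = None,
    score_col: str = "score",
    strict_alleles: bool = False,
) -> list[dict[str, Any]]:
    """Rows supporting presence for one variant, with allele audit flags."""
    rows = table.get(variant.rsid, [])
    if not rows:
        key = f"{variant.chrom}:{variant.pos}:{variant.ref}:{variant.alt}"
        rows = table.get(key) or table.get(f"{variant.chrom}:{variant.pos}", [])
    out = []
    for rec in rows:
        if min_score is not None:
            try:
                if float(rec.get(score_col, "nan")) < min_score:
                    continue
            except (TypeError, ValueError):
                continue
        rec = dict(rec)
        match = _allele_match(variant, rec)
        rec["allele_mismatch"] = match is False
        if strict_alleles and match is False:
            continue
        out.append(rec)
    return out


def evaluate(variant: Variant, catalog: EvidenceCatalog) -> EvidenceProfile:
    """Resolve all evidence for one variant.

    Regional indicators hold iff a stab at ``pos - 1`` hits >= 1 interval
    of the category.  CATO holds iff an rsID-keyed record exists (above
    ``cato_min`` if set).  The eQTL indicator is source-agnostic: a
    significant record from any configured source suffices.  Absence of
    every annotation is a valid profile, not an error.
    """
    cfg = catalog.config
    details: dict[str, list[Any]] = {}
    for cat in REGIONAL_SCORED:
        details[cat] = catalog.index_for(cat).stab(variant.chrom, variant.pos0)
    details["cato"] = _table_lookup(
        variant, catalog.cato,
        min_score=cfg.cato_min, strict_alleles=cfg.strict_alleles,
    )
    details["eqtl"] = _table_lookup(
        variant, catalog.eqtl,
        min_score=cfg.eqtl_min_stat, score_col="statistic",
        strict_alleles=cfg.strict_alleles,
    )

    report: dict[str, Any] = {}
    for cat in ("chromatin_state", "sgrna"):
        hits = catalog.index_for(cat).stab(variant.chrom, variant.pos0)
        if hits:
            report[cat] = hits
    for cat in TABLE_REPORT:
        rows = _table_lookup(variant, getattr(catalog, cat))
        if rows:
            report[cat] = rows
    gene = closest_gene(variant, catalog.genes)
    if gene is not None:
        report["closest_gene"] = gene

    profile = EvidenceProfile(details=details, report_only=report)
    for cat in SCORED_CATEGORIES:
        setattr(profile, f"has_{cat}", bool(details[cat]))
    return profile


def closest_gene(
    variant: Variant, genes: IntervalIndex
) -> tuple[str, int] | None:
    """Closest gene on the variant's chromosome, with signed edge distance.

    Distance 0 inside a gene.  Otherwise the distance to the nearer gene
    edge: positive if the gene starts downstream of (after) the variant,
    negative if it ends upstream.  Ties on |distance| break by (smaller
    start, lexicographic name).  Returns ``None`` when no gene is loaded
    on that chromosome ("no gene" sentinel).
    """
    inside = genes.stab(variant.chrom, variant.pos0)
    if inside:
        best = min(inside, key=lambda iv: (iv.start, iv.name))
        return (best.name or best.source, 0)
    best_key = None
    best_result = None
    for iv in genes.on_chrom(variant.chrom):
        if variant.pos0 < iv.start:
            dist = iv.start - variant.pos0
        else:  # variant.pos0 >= iv.end, else it would be inside
            dist = -(variant.pos0 - (iv.end - 1))
        key = (abs(dist), iv.start, iv.name)
        if best_key is None or key < best_key:
            best_key = key
            best_result = (iv.name or iv.source, dist)
    return best_result
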