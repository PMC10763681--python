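"""Variant input, catalog loading, and per-variant evidence resolution."""

import random

import pytest

from regscore.evidence import (
    CatalogConfig,
    CatalogError,
    Variant,
    VariantInputError,
    closest_gene,
    evaluate,
    load_catalog,
    read_variants,
)
from regscore.intervals import GenomicInterval, build_index
from conftest import catalog_config_from_truth


def write_tsv(path, header, rows):
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(r) for r in rows]) + "\n")


class TestReadVariants:
    def test_tsv_field_mapping(self, tmp_path):
        p = tmp_path / "v.tsv"
        write_tsv(p, ["rsid", "chrom", "pos", "ref", "alt"],
                  [["rs1421085", "chr16", "53800954", "T", "C"]])
        (v,) = read_variants(p)
        assert v.rsid == "rs1421085"
        assert v.pos == 53800954
        assert v.pos0 == 53800953
        assert (v.ref, v.alt) == ("T", "C")

    def test_optional_maf_column(self, tmp_path):
        p = tmp_path / "v.tsv"
        write_tsv(p, ["rsid", "chrom", "pos", "ref", "alt", "maf"],
                  [["rs1", "chr1", "100", "A", "G", "0.12"]])
        assert read_variants(p)[0].maf == 0.12

    def test_missing_column_error_lists_found_vs_required(self, tmp_path):
        p = tmp_path / "v.tsv"
        write_tsv(p, ["rsid", "chrom", "pos", "ref"], [["rs1", "chr1", "1", "A"]])
        with pytest.raises(VariantInputError, match="alt"):
            read_variants(p)

    def test_position_zero_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        write_tsv(p, ["rsid", "chrom", "pos", "ref", "alt"],
                  [["rs1", "chr1", "0", "A", "G"]])
        with pytest.raises(VariantInputError, match="1-based"):
            read_variants(p)

    def test_exact_duplicates_dropped(self, tmp_path):
        p = tmp_path / "v.tsv"
        row = ["rs1", "chr1", "100", "A", "G"]
        write_tsv(p, ["rsid", "chrom", "pos", "ref", "alt"], [row, row])
        assert len(read_variants(p)) == 1

    def test_conflicting_coordinates_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        write_tsv(p, ["rsid", "chrom", "pos", "ref", "alt"],
                  [["rs1", "chr1", "100", "A", "G"], ["rs1", "chr1", "200", "A", "G"]])
        with pytest.raises(VariantInputError, match="conflicting"):
            read_variants(p)

    def test_vcf_multiallelic_split(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t500\trs77\tA\tG,T\t.\t.\t.\n"
        )
        vs = read_variants(p)
        assert [v.alt for v in vs] == ["G", "T"]
        assert all(v.rsid == "rs77" and v.pos == 500 for v in vs)

    def test_vcf_missing_id_rejected(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t500\t.\tA\tG\t.\t.\t.\n"
        )
        with pytest.raises(VariantInputError, match="ID"):
            read_variants(p)


class TestCatalog:
    def test_unknown_category_rejected(self):
        with pytest.raises(CatalogError, match="unknown"):
            CatalogConfig.from_paths(nonsense="x.bed")

    def test_missing_path_names_category_and_path(self, tmp_path):
        cfg = CatalogConfig.from_paths(dnase=tmp_path / "absent.bed")
        with pytest.raises(CatalogError, match="dnase.*absent.bed"):
            load_catalog(cfg)

    def test_empty_config_scores_everything_zero(self):
        catalog = load_catalog(CatalogConfig())
        v = Variant("rs1", "chr1", 100, "A", "G")
        profile = evaluate(v, catalog)
        assert profile.flags == (False,) * 6
        assert set(catalog.empty_scored_categories) == {
            "dnase", "histone", "tf_motif", "abc", "cato", "eqtl"
        }

    def test_source_union_split_tracks_equivalent(self, tmp_path, truth):
        # splitting one category across two files never changes a profile
        lines = truth.files["dnase"].read_text().splitlines(keepends=True)
        half = len(lines) // 2
        (tmp_path / "a.bed").write_text("".join(lines[:half]))
        (tmp_path / "b.bed").write_text("".join(lines[half:]))
        single = load_catalog(CatalogConfig.from_paths(dnase=truth.files["dnase"]))
        split = load_catalog(
            CatalogConfig.from_paths(dnase=[tmp_path / "a.bed", tmp_path / "b.bed"])
        )
        for v in truth.variants[:200]:
            assert evaluate(v, single).has_dnase == evaluate(v, split).has_dnase

    def test_eqtl_source_vocabulary_enforced(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        write_tsv(p, ["rsid", "source", "gene", "effect_allele"],
                  [["rs1", "mystery_db", "GENEA", "G"]])
        with pytest.raises(CatalogError, match="mystery_db"):
            load_catalog(CatalogConfig.from_paths(eqtl=p))


def tiny_catalog(tmp_path, *, cato_rows=(), eqtl_rows=(), **options):
    """A handcrafted catalog around a single variant at chr1:1000 (1-based)."""
    (tmp_path / "d.bed").write_text("chr1\t900\t1100\thotspot\n")
    (tmp_path / "h.broadPeak").write_text("chr1\t950\t1050\tmark\t0\t.\t1\t-1\t-1\n")
    (tmp_path / "m.bed").write_text("chr1\t990\t1010\tMOTIF1\n")
    (tmp_path / "a.bed").write_text("chr1\t800\t1200\tabc_region\n")
    write_tsv(tmp_path / "cato.tsv", ["rsid", "allele", "score"], list(cato_rows))
    write_tsv(tmp_path / "eqtl.tsv",
              ["rsid", "source", "gene", "effect_allele", "statistic"],
              list(eqtl_rows))
    return load_catalog(CatalogConfig.from_paths(
        dnase=tmp_path / "d.bed", histone=tmp_path / "h.broadPeak",
        tf_motif=tmp_path / "m.bed", abc=tmp_path / "a.bed",
        cato=tmp_path / "cato.tsv", eqtl=tmp_path / "eqtl.tsv", **options,
    ))


class TestEvaluate:
    VARIANT = Variant("rs1421085", "chr1", 1000, "T", "C")

    def test_worked_profile_all_but_cato(self, tmp_path):
        # regional overlaps + eQTL present, CATO absent -> (T,T,T,F,T,T)
        cat = tiny_catalog(
            tmp_path,
            eqtl_rows=[["rs1421085", "gtex", "IRX3", "C", "20"]],
        )
        profile = evaluate(self.VARIANT, cat)
        assert profile.flags == (True, True, True, False, True, True)
        profile.check_consistency()

    def test_dual_source_eqtl_details(self, tmp_path):
        cat = tiny_catalog(
            tmp_path,
            eqtl_rows=[
                ["rs1421085", "gtex", "IRX3", "C", "20"],
                ["rs1421085", "eqtlgen", "IRX3", "C", "30"],
            ],
        )
        profile = evaluate(self.VARIANT, cat)
        assert profile.has_eqtl
        assert len(profile.details["eqtl"]) == 2
        assert {r["source"] for r in profile.details["eqtl"]} == {"gtex", "eqtlgen"}

    def test_absent_everywhere_is_all_false(self, tmp_path):
        cat = tiny_catalog(tmp_path)
        profile = evaluate(Variant("rs9", "chr9", 1000, "A", "G"), cat)
        assert profile.flags == (False,) * 6
        profile.check_consistency()

    def test_cato_threshold(self, tmp_path):
        rows = [["rs1421085", "C", "0.05"]]
        lenient = tiny_catalog(tmp_path, cato_rows=rows)
        assert evaluate(self.VARIANT, lenient).has_cato
        strict = tiny_catalog(tmp_path, cato_rows=rows, cato_min=0.1)
        assert not evaluate(self.VARIANT, strict).has_cato

    def test_allele_mismatch_lenient_vs_strict(self, tmp_path):
        rows = [["rs1421085", "A", "0.9"]]  # names neither T nor C
        lenient = tiny_catalog(tmp_path, cato_rows=rows)
        prof = evaluate(self.VARIANT, lenient)
        assert prof.has_cato
        assert prof.details["cato"][0]["allele_mismatch"] is True
        strict = tiny_catalog(tmp_path, cato_rows=rows, strict_alleles=True)
        assert not evaluate(self.VARIANT, strict).has_cato

    def test_planted_truth_recovered_exactly(self, truth, scored):
        for sv in scored:
            assert sv.profile.flags == truth.flags[sv.variant.rsid]

    def test_flag_details_consistency_on_fixture(self, scored):
        for sv in scored:
            sv.profile.check_consistency()


class TestClosestGene:
    def genes(self):
        return build_index([
            GenomicInterval("chr1", 1000, 2000, name="A", source="genes"),
            GenomicInterval("chr1", 5000, 6000, name="B", source="genes"),
        ])

    def test_inside_gene_distance_zero(self):
        v = Variant("rs1", "chr1", 1500, "A", "G")
        assert closest_gene(v, self.genes()) == ("A", 0)

    def test_tie_breaks_to_smaller_start(self):
        genes = build_index([
            GenomicInterval("chr1", 1000, 2000, name="A", source="genes"),
            GenomicInterval("chr1", 5001, 6000, name="B", source="genes"),
        ])
        # pos0=3500 is 1501 bp from A's last base (1999) and from B's start
        v = Variant("rs1", "chr1", 3501, "A", "G")
        name, dist = closest_gene(v, genes)
        assert name == "A"  # tie broken by smaller start
        assert dist == -1501  # gene A ends upstream of the variant

    def test_no_genes_sentinel(self):
        v = Variant("rs1", "chr2", 100, "A", "G")
        assert closest_gene(v, self.genes()) is None

    def test_brute_force_oracle(self, truth, catalog):
        genes = catalog.genes
        rng = random.Random(5)
        sample = rng.sample(truth.variants, 50)
        for v in sample:
            got = closest_gene(v, genes)
            # independent scan over every gene on the chromosome
            best = None
            for iv in genes.on_chrom(v.chrom):
                if iv.start <= v.pos0 < iv.end:
                    d = 0
                elif v.pos0 < iv.start:
                    d = iv.start - v.pos0
                else:
                    d = -(v.pos0 - (iv.end - 1))
                key = (abs(d), iv.start, iv.name)
                if best is None or key < best[0]:
                    best = (key, (iv.name, d))
            assert got == (best[1] if best else None)
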