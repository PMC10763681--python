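"""Score a single SNP against a small hand-built evidence catalog.

Builds a catalog in a temporary directory containing a DNase I hotspot, a
histone-mark broadPeak, a TF motif hit and an enhancer-contact (ABC)
region that all overlap the variant, plus a two-source eQTL record for its
rsID — but no allele-specific TF-occupancy (CATO) record.  Four regional
overlaps and the eQTL are worth 2+2+1+2+2 = 9 of the 10 possible points;
the missing CATO record costs the last point.
"""

import tempfile
from pathlib import Path

from regscore import CatalogConfig, Variant, evaluate, load_catalog, score_profile

variant = Variant(rsid="rs1421085", chrom="chr16", pos=53800954, ref="T", alt="C")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    p0 = variant.pos0
    (tmp / "dnase.bed").write_text(f"chr16\t{p0 - 500}\t{p0 + 500}\thotspot\n")
    (tmp / "histone.broadPeak").write_text(
        f"chr16\t{p0 - 300}\t{p0 + 700}\tH3K4me1_peak\t0\t.\t2.5\t-1\t-1\n"
    )
    (tmp / "motifs.bed").write_text(f"chr16\t{p0 - 8}\t{p0 + 9}\tMOTIF_A\n")
    (tmp / "abc.bed").write_text(f"chr16\t{p0 - 2000}\t{p0 + 2000}\tenhancer_contact\n")
    (tmp / "eqtl.tsv").write_text(
        "rsid\tsource\tgene\teffect_allele\tstatistic\n"
        "rs1421085\tgtex\tIRX3\tC\t25.1\n"
        "rs1421085\teqtlgen\tFTO\tC\t18.3\n"
    )
    (tmp / "cato.tsv").write_text("rsid\tallele\tscore\n")  # no record for this SNP

    catalog = load_catalog(CatalogConfig.from_paths(
        dnase=tmp / "dnase.bed", histone=tmp / "histone.broadPeak",
        tf_motif=tmp / "motifs.bed", abc=tmp / "abc.bed",
        eqtl=tmp / "eqtl.tsv", cato=tmp / "cato.tsv",
    ))
    profile = evaluate(variant, catalog)
    breakdown = score_profile(profile)

print(f"{variant.rsid} evidence flags (dnase, histone, tf_motif, cato, abc, eqtl):")
print("  ", profile.flags)
print("points awarded:", breakdown.awarded)
print("total score:", breakdown.total, "/ 10")
print()
print("A 9 means every evidence line is present except the allele-specific")
print("TF-occupancy score; the eQTL details name the putative target genes:")
for row in profile.details["eqtl"]:
    print(f"   {row['source']:8s} -> {row['gene']} (effect allele {row['effect_allele']})")
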