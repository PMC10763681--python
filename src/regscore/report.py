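"""Serialization of scored variants: TSV table, JSON details, static HTML.

The TSV is the stable, machine-diffable surface (fixed column order, no
timestamps); the JSON carries the full per-variant evidence details — the
machine twin of a per-rsID result page; the HTML renderer produces one
self-contained page per rsID from a stdlib string template.
"""

from __future__ import annotations

import json
from pathlib import Path
from string import Template
from typing import Any, Iterable, Mapping

import pandas as pd

from .evidence import SCORED_CATEGORIES
from .intervals import GenomicInterval
from .scoring import ScoredVariant

__all__ = [
    "write_score_table",
    "read_score_table",
    "scored_to_dict",
    "write_score_json",
    "render_html",
]

SCORE_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt", "score",
    "dnase_pts", "histone_pts", "tf_motif_pts", "cato_pts", "abc_pts", "eqtl_pts",
    "categories_missing", "closest_gene", "cadd", "phylop",
]


def _detail_to_dict(d: Any) -> Any:
    if isinstance(d, GenomicInterval):
        return {
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "name": d.name, "source": d.source, "extra": list(d.extra),
        }
    if isinstance(d, Mapping):
        return {k: v for k, v in d.items()}
    return d


def _report_value(sv: ScoredVariant, table: str) -> str:
    rows = sv.profile.report_only.get(table)
    if not rows:
        return ""
    return str(rows[0].get("score", ""))


def _closest_gene_str(sv: ScoredVariant) -> str:
    cg = sv.profile.report_only.get("closest_gene")
    if cg is None:
        return ""
    name, dist = cg
    return f"{name}:{dist:+d}" if dist else f"{name}:0"


def score_table_rows(scored: Iterable[ScoredVariant]) -> list[dict[str, Any]]:
    rows = []
    for sv in scored:
        v = sv.variant
        row: dict[str, Any] = {
            "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": ",".join(sv.alts), "score": sv.score,
        }
        for cat in SCORED_CATEGORIES:
            row[f"{cat}_pts"] = sv.breakdown.awarded[cat]
        row["categories_missing"] = ",".join(sv.categories_missing)
        row["closest_gene"] = _closest_gene_str(sv)
        row["cadd"] = _report_value(sv, "cadd")
        row["phylop"] = _report_value(sv, "phylop")
        rows.append(row)
    return rows


def write_score_table(scored: Iterable[ScoredVariant], path: str | Path) -> None:
    """Write the per-rsID score table as TSV with a stable column order."""
    df = pd.DataFrame(score_table_rows(scored), columns=SCORE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> dict[str, int]:
    """rsID -> score map from a score table (or any TSV with rsid, score)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "rsid" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: needs 'rsid' and 'score' columns")
    return {str(r): int(s) for r, s in zip(df["rsid"], df["score"])}


def scored_to_dict(sv: ScoredVariant) -> dict[str, Any]:
    """Full evidence record for one rsID (JSON-serializable)."""
    v = sv.variant
    report = {}
    for key, val in sv.profile.report_only.items():
        if key == "closest_gene":
            report[key] = {"gene": val[0], "distance": val[1]}
        else:
            report[key] = [_detail_to_dict(d) for d in val]
    return {
        "rsid": v.rsid,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alts": sv.alts,
        "maf": v.maf,
        "score": sv.score,
        "points": dict(sv.breakdown.awarded),
        "evidence": {
            cat: {
                "present": sv.profile.flag(cat),
                "details": [_detail_to_dict(d) for d in sv.profile.details[cat]],
            }
            for cat in SCORED_CATEGORIES
        },
        "report_only": report,
        "categories_missing": sv.categories_missing,
    }


def write_score_json(scored: Iterable[ScoredVariant], path: str | Path) -> None:
    payload = {sv.variant.rsid: scored_to_dict(sv) for sv in scored}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$rsid</title></head>
<body>
<h1>$rsid &mdash; regulatory evidence score $score / 10</h1>
<p>$chrom:$pos $ref&gt;$alts</p>
<table border="1" cellpadding="4">
<tr><th>evidence</th><th>present</th><th>points</th><th>details</th></tr>
$rows
</table>
<h2>Report-only annotations</h2>
<pre>$report</pre>
</body></html>
"""
)


def render_html(sv: ScoredVariant) -> str:
    """One self-contained page listing every evidence detail and the
    score breakdown for one rsID."""
    d = scored_to_dict(sv)
    rows = []
    for cat in SCORED_CATEGORIES:
        ev = d["evidence"][cat]
        detail = json.dumps(ev["details"]) if ev["details"] else "&mdash;"
        rows.append(
            f"<tr><td>{cat}</td><td>{'yes' if ev['present'] else 'no'}</td>"
            f"<td>{d['points'][cat]}</td><td>{detail}</td></tr>"
        )
    return _PAGE.substitute(
        rsid=d["rsid"],
        score=d["score"],
        chrom=d["chrom"],
        pos=d["pos"],
        ref=d["ref"],
        alts=",".join(d["alts"]),
        rows="\n".join(rows),
        report=json.dumps(d["report_only"], indent=2),
    )
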