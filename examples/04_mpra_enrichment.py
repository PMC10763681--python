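"""MPRA emVar enrichment by score bin.

Samples 248 expression-modulating variants (emVars) from a synthetic
tested set with selection probability proportional to 2**score, computes
the per-score-bin emVar rate per 1000 reference SNPs, and runs both
enrichment tests.  The same analysis on a uniformly drawn (null) emVar
set shows what no enrichment looks like.
"""

import tempfile
from pathlib import Path

from regscore import (
    FixtureParams,
    emvar_enrichment,
    generate_fixtures,
    generate_mpra_sets,
)

with tempfile.TemporaryDirectory() as tmp:
    truth = generate_fixtures(FixtureParams(seed=7), Path(tmp))

for label, strength in [("enriched (w=2)", 2.0), ("null (w=1)", 1.0)]:
    emvars, tested = generate_mpra_sets(
        truth, enrichment_strength=strength, n_emvars=248, seed=5
    )
    res = emvar_enrichment(emvars, tested, truth.scores)
    print(f"--- {label}: 248 emVars vs {len(tested)} tested variants")
    print("score  n_emvar  n_ref  emVars per 1000")
    for s in sorted(res.per_bin):
        n_set, n_ref, rate = res.per_bin[s]
        print(f"  {s:2d}    {n_set:5d} {n_ref:6d}  {rate:8.1f}")
    print(f"{res.method}: t = {res.statistic:+.3f}, p = {res.pvalue:.4g}")
    print(f"{res.secondary_method}: U = {res.secondary_statistic:.0f}, "
          f"p = {res.secondary_pvalue:.4g}")
    print()

print("Rising per-1000 rates across score bins mean functional variants")
print("concentrate at high scores.  The Mann-Whitney test on per-variant")
print("scores carries most of the power; the paired t-test over 11 bin")
print("pairs is conservative and serves as a bin-level cross-check.")
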