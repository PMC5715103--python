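"""Parse a RepeatMasker catalogue, characterise it, and apply the exclusion
filters (mono-repeats out; >5% divergence/deletion/insertion out)."""

import io

from strseek.catalog import filter_catalog, parse_repeatmasker, summarize_catalog
from strseek.simulate import CatalogConfig, gen_catalog

# a synthetic .out file standing in for a genome-wide RepeatMasker run
out_text, _ = gen_catalog(CatalogConfig(n_loci=5000), seed=1)
loci = parse_repeatmasker(io.StringIO(out_text))  # Simple_repeat rows only

summary = summarize_catalog(loci)
print(f"{summary.n_total} simple-repeat loci parsed")
print("loci by period (motif length):", summary.period_counts)
print("loci by motif GC% bin:", summary.gc_histogram)

kept, report = filter_catalog(loci, exclude_mono=True, max_pct=5.0)
print(
    f"\nfilters: {report.n_excluded_mono} mono-repeats excluded, "
    f"{report.n_excluded_divergent} divergent (>5%) excluded, "
    f"{report.n_kept} kept of {report.n_input} "
    f"({100 * report.n_kept / (report.n_input - report.n_excluded_mono):.0f}% of non-mono)"
)
# The kept fraction is the pool of clean, fragment-analysis-genotypable STRs
# that the downstream polymorphism cross-reference starts from.
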