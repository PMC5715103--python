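"""From STR-caller ALLREADS fields to filtered, FPKM-normalised expression,
plus the two qPCR relative-expression calculations."""

from strseek.expression import (
    AlleleReadProfile,
    CtMeasurement,
    filter_alleles,
    normalize_expression,
    observed_alleles,
    parse_allreads,
    rel_expr_dct,
    rel_expr_ddct,
)

# one locus in one tumor sample: allele (bp offset) -> supporting reads
reads = parse_allreads("-2|12;0|25;2|9")
profile = AlleleReadProfile("P1", "tumor", "TG-PCA3", reads, total_mapped_reads=23_331_172)

filtered = filter_alleles(profile, min_reads=10)  # the 9-read allele drops out
print("alleles surviving the 10-read rule:", dict(filtered.allele_reads))

fpkm = normalize_expression(filtered, locus_length_bp=26, scheme="fpkm")
print(f"FPKM over the 26 bp locus: {fpkm:.1f}")

alleles = observed_alleles([filtered])
print("observed allele labels (ascending):", alleles)

# qPCR: delta-delta-Ct fold change (one housekeeper) and 2^-dCt abundance
# (geometric mean of two housekeepers)
fold = rel_expr_ddct(CtMeasurement(24.1, [15.0]), CtMeasurement(25.6, [15.2]))
print(f"ddCt fold change, treated vs control: {fold:.2f}x")
abundance = rel_expr_dct(CtMeasurement(26.0, [22.0, 24.0]))
print(f"2^-dCt relative abundance: {abundance:.4f}")
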