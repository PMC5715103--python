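"""Classify STR loci into promoter / 5'UTR / CDS / intron / 3'UTR /
intergenic against gene models, and summarise the composition."""

from strseek.annotation import FeatureClassifier, GeneModel, composition
from strseek.catalog import STRLocus

# a coding gene (two exons, CDS inside) and a non-coding lncRNA
gene = GeneModel("KLK3", "chr19", "+", 1000, 2000, 1200, 1800, ((1000, 1400), (1600, 2000)))
lnc = GeneModel("PCA3", "chr9", "-", 79_395_000, 79_401_000, 79_395_000, 79_395_000,
                ((79_395_000, 79_396_000), (79_400_000, 79_401_000)))

classifier = FeatureClassifier([gene, lnc], promoter_bp=2000)


def show(label, locus):
    print(f"{label:28s} -> {classifier.classify(locus)}")


show("inside the CDS", STRLocus("chr19", 1250, 1270, "CAG", 3, "+", 0, 0, 0))
show("exonic, before the CDS", STRLocus("chr19", 1050, 1070, "TG", 2, "+", 0, 0, 0))
show("between the exons", STRLocus("chr19", 1450, 1470, "TG", 2, "+", 0, 0, 0))
show("500 bp upstream of the TSS", STRLocus("chr19", 480, 520, "TG", 2, "+", 0, 0, 0))
show("exon of the lncRNA", STRLocus("chr9", 79_400_650, 79_400_676, "TG", 2, "+", 0, 0, 0))
show("nowhere near a gene", STRLocus("chr19", 50_000, 50_020, "TG", 2, "+", 0, 0, 0))

loci = [
    STRLocus("chr19", s, s + 20, "TG", 2, "+", 0, 0, 0)
    for s in (1250, 1050, 1450, 480, 50_000, 60_000, 70_000)
]
comp = composition(classifier.classify(l) for l in loci)
print("\ncomposition (% of loci):", {k: round(v, 1) for k, v in comp.items()})
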