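"""Shared genotype codes.

Parental genotype calls at heterozygous SNP sites of an F1 hybrid are
coded as integers throughout the package:

* ``HOM0`` — homozygous for the haplotype-0 (C57, maternal) allele
* ``HOM1`` — homozygous for the haplotype-1 (DBA, paternal) allele
* ``HET``  — both alleles observed (uninformative for parental state in a
  haploid; the signal of extra chromatids in diploids/aneuploids)
* ``MISSING`` — site not observed (allele dropout / no coverage)
"""

HOM0 = 0
HOM1 = 1
HET = 2
MISSING = -1

GT_TO_STRING = {HOM0: "0/0", HOM1: "1/1", HET: "0/1", MISSING: "./."}
STRING_TO_GT = {v: k for k, v in GT_TO_STRING.items()}
STRING_TO_GT["1/0"] = HET
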