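# Default miRNA slot scheme.
# Closed-class slots list their published terms; Order is open-class and
# matched by pattern (numbering strings such as 21, 181b, 16a1, 128c).
# Hairpin (3p/5p arms) and Loci (genomic locus digit) are generalized by
# the abstract Suffix slot; Let (let/lin indicator family) specializes
# the miRNA indicator slot.
VERSION 1
SLOT Species
  hsa
  cel
SLOT Precursor
  pre
  pri
SLOT miRNA
  mir
  mirna
  microrna
  micro rna
  let
  lsy
SLOT Let PARENT miRNA
  let
  lin
SLOT Order OPEN ^\d{1,4}[a-z]{0,2}\d?$
SLOT Conj
  and
  or
SLOT Suffix
SLOT Hairpin PARENT Suffix
  3p
  5p
SLOT Loci PARENT Suffix OPEN ^[1-9]$
SLOT Prefix
  oncomir
  anti
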