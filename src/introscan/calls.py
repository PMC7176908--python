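"""Call vocabularies shared across modules.

Raw array calls use Illumina-style A/B allele notation: ``AA``, ``BB``
(homozygotes), ``AB`` (heterozygote), ``NC`` (no call).  After encoding against
the two parents, graphical-genotype calls are single letters: ``A`` (recurrent
parent homozygote), ``B`` (donor homozygote), ``H`` (heterozygote), ``NA``
(missing).
"""

# raw (allele-pair) calls
HOM_A = "AA"
HOM_B = "BB"
HET = "AB"
NO_CALL = "NC"
RAW_CALLS = (HOM_A, HET, HOM_B, NO_CALL)
HOM_CALLS = (HOM_A, HOM_B)

# encoded graphical-genotype calls
REC = "A"  # recurrent-parent homozygote
DON = "B"  # donor homozygote
HET_ENC = "H"
MISSING = "NA"
ENCODED_CALLS = (REC, DON, HET_ENC, MISSING)

# phenotype classes
TRANSFORMABLE = "transformable"
NON_TRANSFORMABLE = "non_transformable"
UNKNOWN = "unknown"
PHENOTYPE_CLASSES = (TRANSFORMABLE, NON_TRANSFORMABLE, UNKNOWN)
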