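"""Desk calculations: from raw cross counts to the headline drive rates.

Turns pooled phenotype counts into the drive inheritance rate, converts it
to the germline drive-conversion rate, averages the two sexes, infers the
embryo resistance-allele formation rate from a sterility assay, and
computes the genetic load a suppression drive must impose to shrink a
robust cage population.
"""

from homingdrive.cross_stats import (
    CrossCounts,
    SterilityCounts,
    average_conversion,
    conversion_from_inheritance,
    embryo_rate_from_sterility,
    inheritance_rate,
)
from homingdrive.model import required_genetic_load

# Pooled offspring of drive/Cas9-heterozygous parents crossed to wild-type:
# drive carriers are scored by DsRed fluorescence.
female_cross = CrossCounts("female", offspring_with_drive=864, offspring_without_drive=136)
male_cross = CrossCounts("male", offspring_with_drive=904, offspring_without_drive=96)

conversions = {}
for cross in (female_cross, male_cross):
    rate, sem = inheritance_rate(cross)
    conversions[cross.parent_sex] = conversion_from_inheritance(rate)
    print(f"{cross.parent_sex} parents: inheritance {100 * rate:.1f}% "
          f"(SEM {100 * sem:.1f}%), conversion {100 * conversions[cross.parent_sex]:.1f}%")

avg = average_conversion(conversions["female"], conversions["male"])
print(f"sex-averaged conversion rate: {100 * avg:.1f}%")
# Inheritance above the Mendelian 50% measures how often the wild-type
# allele in a heterozygous germline was converted to a drive copy.

# Sterility assay: drive-carrier daughters of drive mothers are sterile if
# the paternal wild-type allele was cleaved (nonfunctionally) in the embryo.
assay = SterilityCounts(sterile=12, assessed=22, baseline_sterile=1, baseline_assessed=20)
embryo = embryo_rate_from_sterility(assay)
print(f"embryo resistance-allele formation rate: {100 * embryo:.1f}%")

# A fly population producing 20 eggs per female with 80% egg-to-adult
# survival replaces itself until the genetic load exceeds:
load = required_genetic_load(eggs_per_female=20, egg_to_adult_survival=0.8)
print(f"required genetic load for suppression: {load:.3f}")
# i.e. more than 7 of every 8 females must be effectively sterilised.
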