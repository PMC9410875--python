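"""Published reference inputs used throughout the package.

These are experimental printed values (sequences, masses, affinities) that
the analyses consume as inputs; they are not fitted or tuned here.
"""

from __future__ import annotations

from .binding_model import SiteAffinities
from .itc_model import ITCProtocol
from .sequence_motif import ConsensusPattern, DnaSequence

__all__ = [
    "P53_DNA",
    "DBE2_DNA",
    "FBE_CONSENSUS",
    "FBE2_PATTERN",
    "FOXL2_DBD_MASS_KDA",
    "FOXA1_DBD_MASS_KDA",
    "FOXO3_DBD_MASS_KDA",
    "COMPLEX_MASS_DBE2_KDA",
    "COMPLEX_MASS_P53_KDA",
    "DBE2_KD_UM",
    "DEFAULT_WT_PARAMS",
    "DEFAULT_D_TOTAL",
    "DEFAULT_MOLAR_RATIOS",
    "DEFAULT_ITC_PROTOCOL",
    "P53_ITC_PROTOCOL",
]

#: The 16-mer duplex from the TP53 promoter carrying the homotypic FBE1/FBE2
#: cluster (FBE1 = TATTTAT read on the reverse strand; FBE2 = ATTATCG).
P53_DNA = DnaSequence("p53-DNA", "AAATATTTATTATCGA")

#: Canonical single-site control duplex (Daf-16 family binding element 2).
DBE2_DNA = DnaSequence("DBE2-DNA", "CAAAATGTAAACAAGT")

#: The typical forkhead binding element consensus.
FBE_CONSENSUS = ConsensusPattern("RYAAAYA", name="FBE")

#: The second, non-canonical site revealed by groove allostery.
FBE2_PATTERN = ConsensusPattern("ATTATCG", name="FBE2")

# SEC-MALS solution masses (kDa).
FOXL2_DBD_MASS_KDA = 12.4
FOXA1_DBD_MASS_KDA = 12.5
FOXO3_DBD_MASS_KDA = 12.3
COMPLEX_MASS_DBE2_KDA = 20.1
COMPLEX_MASS_P53_KDA = 32.7

#: Single-site dissociation constant of FOXL2-DBD for DBE2 DNA (uM).
DBE2_KD_UM = 0.79

#: Demo/test convention for the wild-type two-site probe: both microscopic
#: constants anchored to the DBE2 single-site KD, moderate positive
#: cooperativity.  A convention, not a fitted value.
DEFAULT_WT_PARAMS = SiteAffinities(k1=1.27e6, k2=1.27e6, omega=3.0)

#: EMSA probe concentration (molar).
DEFAULT_D_TOTAL = 2.5e-6

#: Protein:DNA molar ratios spanning sub- to super-stoichiometric lanes.
DEFAULT_MOLAR_RATIOS = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0)

#: Instrument-typical schedule for the single-site runs: 200 ul cell with
#: 50 uM DNA, 20 x 2.5 ul injections of 750 uM protein.
DEFAULT_ITC_PROTOCOL = ITCProtocol(
    cell_volume=200e-6,
    cell_conc=50e-6,
    syringe_conc=750e-6,
    injection_volumes=(2.5e-6,) * 20,
)

#: The two-site probe schedule: 40 x 2 ul injections of 850 uM protein.
P53_ITC_PROTOCOL = ITCProtocol(
    cell_volume=200e-6,
    cell_conc=50e-6,
    syringe_conc=850e-6,
    injection_volumes=(2.0e-6,) * 40,
)
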