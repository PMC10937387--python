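"""Published study inputs: printed cohort counts and packaged fixtures.

The counts below are the printed results of the SRPK3/TTN myopathy study
and its comparison cohorts; they are inputs to the enrichment and
co-occurrence statistics, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

from .pedigree import Pedigree, read_pedigrees
from .variants import CohortCounts

#: 25 index families, 21 of which carry a truncating TTN variant
SRPK3_COHORT = CohortCounts("SRPK3", n_units=25, n_ttn_truncating=21, unit="family")

#: limb-girdle muscular dystrophy comparison cohorts (per-patient counts)
LGMD_R1 = CohortCounts("LGMD-R1", n_units=170, n_ttn_truncating=5, unit="individual")
LGMD_R2 = CohortCounts("LGMD-R2", n_units=94, n_ttn_truncating=1, unit="individual")
LGMD_R12 = CohortCounts("LGMD-R12", n_units=56, n_ttn_truncating=2, unit="individual")

#: reference-population co-occurrence check: hemizygous SRPK3
#: loss-of-function males among gnomAD males, none carrying a TTNtv
GNOMAD_MALES = 76_702
GNOMAD_SRPK3_LOF_MALES = 6
GNOMAD_LOF_WITH_TTNTV = 0

#: printed truncating-carrier fraction in the reference population (~1%)
POPULATION_TTNTV_CARRIER_FREQ = 0.01


def load_study_families() -> list[Pedigree]:
    """Families M, Y and Z reconstructed from their published descriptions.

    A synthetic stand-in: named members carry their published sex,
    affection, two-locus status and X-inactivation calls, but the
    connecting structure is inferred (no machine-readable pedigrees are
    published).
    """
    with resources.as_file(
        resources.files("digenic.data") / "study_families_MYZ_synthetic.ped"
    ) as p:
        return read_pedigrees(p)
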