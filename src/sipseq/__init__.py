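"""sipseq: DNA stable-isotope probing analysis toolkit.

Pipeline stages, in the order a SIP-metagenomics experiment runs:

1. :mod:`sipseq.sipsim` — forward simulation of CsCl-gradient SIP
   experiments (and :mod:`sipseq.seqgen` for sequence-level synthesis);
2. :mod:`sipseq.gradient` — refractive-index to density conversion and
   heavy/light fraction pooling;
3. :mod:`sipseq.labelcall` — the three-criterion labelled-taxon classifier;
4. :mod:`sipseq.consumption` — headspace gas accounting and harvest timing;
5. :mod:`sipseq.alignkit` — exact affine-gap pairwise alignment core;
6. :mod:`sipseq.relatedness` — ANI / RBH-AAI / TETRA, species calls, MAG
   quality filtering and dereplication;
7. :mod:`sipseq.sdimo` — SDIMO marker screening, group assignment and
   fragment-recruitment abundance.
"""

from importlib import resources

from . import alignkit, consumption, gradient, labelcall, relatedness, sdimo, seqgen, sipsim
from .alignkit import Alignment, ScoringScheme, global_align, local_align
from .consumption import HeadspaceSeries, consumption_rate, cumulative_consumption, harvest_time
from .gradient import PoolPair, PoolWindows, density_from_ri, pool_fractions, ri_from_density
from .labelcall import AbundanceQuad, LabelCall, classify_from_pools, classify_labelled, evaluate_recovery
from .relatedness import GenomeRecord, aai, ani, dereplicate, quality_filter, same_species, tetra_correlation
from .sdimo import find_markers, recruit_abundance, screen_report, synthetic_panel
from .sipsim import CommunityProfile, GradientParams, SIPDesign, Taxon, default_community, simulate_experiment

__version__ = "0.1.0"


def bundled_mag_quality_path():
    """Path to the bundled gas-seep MAG/isolate quality summary TSV."""
    return resources.files("sipseq") / "data" / "mag_quality_summary.tsv"
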