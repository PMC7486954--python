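"""Published summary data for the Emiliania huxleyi mutation-accumulation study.

These are the printed per-line exposures and headline counts of the
E. huxleyi MA experiment (15 diploid lines bottlenecked to one cell
every 14 days for 8 months), used as inputs when re-deriving the
study's rate, spectrum and selection estimates.  Raw sequencing data
are not required for any of these derivations.
"""

from __future__ import annotations

import pandas as pd

from .genome import experiment_table

# Per MA line: generations elapsed, callable nuclear sites, accepted de
# novo single-nucleotide substitutions.
EHUX_LINES = [
    ("Eh_mut_A", 210, 118_881_543, 34),
    ("Eh_mut_E", 209, 119_008_226, 22),
    ("Eh_mut_G", 209, 120_234_404, 40),
    ("Eh_mut_H", 221, 117_447_180, 44),
    ("Eh_mut_J", 267, 117_688_670, 40),
    ("Eh_mut_M", 285, 120_186_108, 19),
    ("Eh_mut_N", 273, 117_776_564, 30),
    ("Eh_mut_O", 291, 116_961_626, 26),
    ("Eh_mut_R", 202, 120_132_427, 21),
    ("Eh_mut_S", 214, 116_500_955, 52),
    ("Eh_mut_T", 209, 119_224_148, 47),
    ("Eh_mut_U", 200, 117_252_421, 20),
    ("Eh_mut_X", 232, 104_532_863, 23),
    ("Eh_mut_Y", 240, 120_278_083, 25),
    ("Eh_mut_Z", 218, 119_602_275, 12),
]

PLOIDY = 2
GENOME_SIZE = 167_000_000          # assembled nuclear genome, bp
CDS_SIZE = 39_635_709              # annotated coding sequence, nt
GENOMIC_GC = 0.657                 # genome-wide GC fraction

# Pooled strand-symmetric spectrum totals.
N_GC_TO_AT = 151
N_AT_TO_GC = 207

# Per-class counts affecting functional regions.
EFFECT_COUNTS = {
    "UTR": 15,
    "intergenic": 329,
    "intron": 7,
    "missense": 67,
    "splice_region": 3,
    "start_lost": 1,
    "stop_gained": 1,
    "synonymous": 32,
}
CALLABLE_CODING = 30_362_830
CALLABLE_NONCODING = 87_351_003

# Codon-bias inputs: frequency of optimal codons in the 500 most
# actively expressed genes, and the selective-advantage range assumed
# for preferred codons.
FOP_TOP500 = 0.8859
S_COEF_RANGE = (1e-6, 1e-7)

# Population-genetic inputs.
PI_S = 0.006                       # synonymous nucleotide diversity
DS_DIVERGENCE = 0.03               # synonymous divergence to sister species
DIVERGENCE_TIME_YEARS = 290_000
MAX_GENERATIONS_PER_YEAR = 300


def ehux_experiment() -> pd.DataFrame:
    """The 15-line experiment table (generations, callable sites, counts)."""
    return experiment_table(EHUX_LINES, genome_size=GENOME_SIZE)
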