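"""Bundled reference tables.

Small published summary tables shipped with the package so worked
examples and aggregate checks run without downloads.
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = ["example_diversity_table"]

# Per-locality genomic diversity from a published RAD-seq survey of
# tetraploid Alkanna sampled across Greece and Crete: sample size N,
# per-base nucleotide diversity pi, expected heterozygosity He, the
# inbreeding coefficient F_IS, and the count p of private alleles.
# Localities are grouped into the survey's regional pools (the two
# Cretan localities belong to a sister species and form their own
# group).
_DIVERSITY_TABLE = """\
locality,species,region,n,pi,he,fis,private_alleles
AT28,sieberi,Central Crete,11,0.007,0.101,-0.005,136
AT27,sieberi,Western Crete,11,0.006,0.090,0.071,39
AT01,tinctoria,Southern-Central,9,0.008,0.113,-0.010,6
AT10,tinctoria,Southern-Central,8,0.006,0.097,0.052,25
AT02,tinctoria,Southern-Central,9,0.007,0.105,0.036,8
AT06,tinctoria,Southern-Central,9,0.008,0.110,0.009,9
AT07,tinctoria,Southern-Central,9,0.008,0.116,-0.071,16
AT08,tinctoria,Southern-Central,9,0.007,0.102,0.049,18
AT17,tinctoria,Southern-Central,9,0.007,0.096,0.081,13
AT19,tinctoria,Southern-Central,9,0.006,0.092,0.089,19
AT21,tinctoria,Southern-Central,9,0.006,0.085,0.025,17
AT25,tinctoria,Southern-Central,9,0.006,0.080,-0.036,6
AT03,tinctoria,Northern,11,0.009,0.124,0.030,10
AT04,tinctoria,Northern,9,0.009,0.125,0.059,11
AT13,tinctoria,Northern,8,0.009,0.125,0.011,3
ATA8,tinctoria,Northern,9,0.008,0.110,0.039,14
"""


def example_diversity_table() -> pd.DataFrame:
    """Per-locality diversity statistics for 16 Greek Alkanna localities.

    Columns: locality, species, region, n (individuals), pi (per-base
    nucleotide diversity), he (expected heterozygosity over SNPs), fis,
    private_alleles.  Useful for exercising regional aggregation.
    """
    return pd.read_csv(_io.StringIO(_DIVERSITY_TABLE)).set_index("locality")
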