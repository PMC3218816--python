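"""Small reference tables bundled with the package.

The motivating breast-cancer genome scan in the Women's Health Initiative
trials evaluated 4,988 SNPs with a combined main-effect + intervention-
interaction test and published the 20 top-ranked SNPs with their combined
p-values.  Those printed p-values (and the total test count) are the input
to the rank-based FDR reproduction exercised by the test suite and the
acceptance script; the underlying genotype data are not public, so the
table below is the only real-data surface the package touches.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TOTAL_SNPS_TESTED", "load_top20_scan"]

#: Total number of SNPs evaluated in the published scan.
TOTAL_SNPS_TESTED = 4988

# rank, rsID, chromosome arm, combined-test p, published FDR, gene region
_TOP20 = [
    (1, "rs1219648", "10q26", 6.45e-09, 3.21e-05, "FGFR2"),
    (2, "rs2981579", "10q26", 7.76e-09, 1.94e-05, "FGFR2"),
    (3, "rs3750817", "10q26", 5.61e-08, 9.32e-05, "FGFR2"),
    (4, "rs11200014", "10q26", 1.08e-07, 1.35e-04, "FGFR2"),
    (5, "rs2420946", "10q26", 1.56e-07, 1.56e-04, "FGFR2"),
    (6, "rs2981582", "10q26", 5.25e-07, 4.37e-04, "FGFR2"),
    (7, "rs7705343", "5p12", 5.88e-05, 4.19e-02, "MRPS30"),
    (8, "rs13159598", "5p12", 1.36e-04, 8.46e-02, "MRPS30"),
    (9, "rs11746980", "5p12", 2.40e-04, 1.33e-01, "MRPS30"),
    (10, "rs9790879", "5p12", 2.44e-04, 1.22e-01, "MRPS30"),
    (11, "rs2330572", "5p12", 2.94e-04, 1.33e-01, "MRPS30"),
    (12, "rs7555040", "1p33", 3.36e-04, 1.40e-01, None),
    (13, "rs4415084", "5p12", 4.00e-04, 1.53e-01, "MRPS30"),
    (14, "rs994793", "5p12", 4.17e-04, 1.48e-01, "MRPS30"),
    (15, "rs2218080", "5p12", 4.46e-04, 1.48e-01, "MRPS30"),
    (16, "rs7795554", "7p21", 4.98e-04, 1.55e-01, None),
    (17, "rs7519783", "1q32", 9.04e-04, 2.65e-01, None),
    (18, "rs1499111", "4q28", 1.15e-03, 3.18e-01, None),
    (19, "rs719278", "3q11", 1.22e-03, 3.20e-01, "EPHA6"),
    (20, "rs1232355", "3q26", 1.32e-03, 3.29e-01, None),
]


def load_top20_scan() -> pd.DataFrame:
    """Return the published top-20 scan rows.

    Columns: ``rank`` (published rank), ``snp_id``, ``region`` (chromosome
    arm), ``p_combined`` (combined-test p-value as printed, 3 significant
    figures), ``fdr_published`` (printed rank-based FDR), ``gene``.
    """
    return pd.DataFrame(
        _TOP20,
        columns=["rank", "snp_id", "region", "p_combined", "fdr_published", "gene"],
    )
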