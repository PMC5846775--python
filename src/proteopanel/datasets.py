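"""Bundled reference tables.

``load_protease_table`` returns the published differential-abundance table
of the 17 proteases found to differ between IBS, UC and HC mucosal biopsy
supernatants: per protease, the log10 abundance ratio and unadjusted
p-value for each pairwise group comparison.  It is the canonical input for
the abundance-pattern classifier and a convenient worked example.

The two complement C3 entries share the same UniProt identifier; they are
disambiguated here with ``.1``/``.2`` suffixes (a packaging convention, not
part of the identifier).
"""

from __future__ import annotations

import io

import pandas as pd

_PROTEASE_TABLE_TSV = """\
protein_id	name	log10_ratio_IBS_vs_HC	p_IBS_vs_HC	log10_ratio_UC_vs_HC	p_UC_vs_HC	log10_ratio_IBS_vs_UC	p_IBS_vs_UC
Q96QL8	Elastase 3A	0.63	0.026	0.22	0.870	0.41	0.025
A8MTQ9	Chymotrypsin-C	0.60	0.014	0.21	0.977	0.39	0.003
D3DPS0	Proteasome subunit beta type-2	0.38	0.006	0.10	0.500	0.28	0.034
CO3.1	Complement C3 (unspecified isoform)	0.29	0.016	-0.15	0.366	0.44	0.002
B4DJQ8	Cathepsin C	1.18	0.001	1.10	0.007	0.07	0.493
B3KQK4	Cathepsin L1	0.51	0.005	0.29	0.309	0.22	0.081
DNPEP	Aspartyl aminopeptidase	0.37	0.006	0.24	0.219	0.14	0.276
D3DW86	Proteasome subunit alpha type-4	0.16	0.017	0.05	0.133	0.11	0.113
B2R7F8	Plasminogen	0.27	0.450	-1.33	0.073	1.60	0.006
CO3.2	Complement C3	-0.10	0.823	-1.53	0.014	1.43	0.004
Q5U000	Cathepsin Z	-0.55	0.013	-0.22	0.034	-0.33	0.569
B2CIS9	Caspase 14	-0.49	0.006	-0.18	0.091	-0.31	0.086
Q6IAT9	Proteasome subunit beta type-6	-0.40	0.019	-0.10	0.107	-0.31	0.221
Q5QNR8	Proteasome subunit beta type-8	-0.28	0.007	-0.16	0.043	-0.12	0.315
A8K071	X-prolyl aminopeptidase 1	-0.62	0.016	-0.28	0.640	-0.35	0.037
A8K6H1	Endoplasmic reticulum aminopeptidase 1	-0.26	0.046	0.15	0.519	-0.41	0.012
Q6IBC3	Cathepsin H	-0.31	0.094	0.14	0.338	-0.44	0.020
"""


def load_protease_table() -> pd.DataFrame:
    """The 17-protease differential table (log10 ratios and pairwise p)."""
    df = pd.read_csv(io.StringIO(_PROTEASE_TABLE_TSV), sep="\t", index_col="protein_id")
    return df
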