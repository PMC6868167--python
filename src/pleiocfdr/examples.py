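"""Bundled worked-example dataset.

Eleven loci from a published cross-trait cFDR analysis of chronic pain grade
(CPG, primary trait) against major depressive disorder (MDD, secondary
trait), with the reported per-SNP GWAS effects and p-values, the two
directional cFDR values and the conjunctional ccFDR.  The printed cFDR
columns are inputs here: the underlying genome-wide summary statistics are
not redistributable, so the table serves to exercise the ccFDR max rule and
the significance classification (at the study's threshold of 0.01 it yields
6 CPG-significant, 9 MDD-significant, 11 total and 4 pleiotropic SNPs).

``cfdr_primary_given_secondary`` is the CPG-given-MDD cFDR,
``cfdr_secondary_given_primary`` the MDD-given-CPG cFDR.  Effects are the
CPG beta and the MDD odds ratio for the listed effect allele.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["example_loci"]

_LOCI_TSV = """\
rsid	chrom	pos	effect_allele	other_allele	beta_cpg	p_cpg	or_mdd	p_mdd	cfdr_primary_given_secondary	cfdr_secondary_given_primary	ccfdr
rs4904790	14	42242623	C	T	-0.03	1.44e-03	1.042	1.37e-05	0.02	3.58e-03	0.02
rs1584317	14	42213816	C	G	0.028	4.48e-03	0.96	4.59e-06	0.029	3.57e-03	0.03
rs11846556	14	42183025	A	G	-0.037	1.11e-04	1.05	2.98e-07	5.57e-04	3.76e-05	5.57e-04
rs10131184	14	42166111	A	G	0.035	2.82e-04	0.95	2.53e-08	8.46e-04	7.10e-06	8.46e-04
rs8015100	14	42095232	A	T	-0.033	6.67e-04	1.06	1.50e-09	6.67e-04	9.27e-07	6.67e-04
rs11157241	14	42051771	C	T	0.035	2.91e-04	0.94	4.44e-09	5.83e-04	1.28e-06	5.83e-04
rs10138559	14	41975989	C	T	-0.02	0.03	1.042	1.04e-06	0.1	5.25e-03	0.1
rs10872954	14	41948768	A	G	-0.026	6.45e-03	1.04	7.68e-06	0.053	7.02e-03	0.053
rs149981001	12	60264802	C	T	0.2	6.24e-08	1.087	0.018	1.06e-03	0.018	0.018
rs147573737	12	60231575	C	T	-0.2	2.09e-07	0.917	0.023	2.21e-03	0.023	0.023
rs35641559	1	73760104	C	T	0.02	0.03	0.961	2.08e-06	0.1	8.83e-03	0.1
"""


def example_loci(raw: bool = False) -> pd.DataFrame:
    """The 11-locus example table as a DataFrame (one row per SNP).

    With ``raw=True`` every column is returned as the printed string, so the
    reported precision of each value (e.g. a ccFDR quoted as 0.03) remains
    inspectable.
    """
    if raw:
        return pd.read_csv(StringIO(_LOCI_TSV), sep="\t", dtype=str)
    return pd.read_csv(StringIO(_LOCI_TSV), sep="\t")
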