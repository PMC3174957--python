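"""Worked replication-screen example.

Published-style summary statistics for eight candidate eQTL SNPs screened
for COPD association in two independent cohorts (a family-based screen,
then a case-control screen), together with each SNP's discovery-stage
combined-GWAS odds ratio. The discovery OR/p is missing for two SNPs that
reached candidacy through the meta-analysis only; their meta p-values are
carried instead. These rows exercise the sequential p < 0.1 / p < 0.1 +
direction-consistency replication rule end to end.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = ["replication_screen_example", "screen_frames_from_example"]

_TABLE = """\
snp_id	chrom	bp	gene	screen1_effect	screen1_p	screen2_or	screen2_p	discovery_or	discovery_p	discovery_meta_p
rs1999261	6	6515106	INTERGENIC	Increase	0.042	0.94	0.53	1.15	0.0080
rs1265098	6	31214156	PSORS1C1	Increase	0.024	1.20	0.098	1.18	0.0065
rs4750277	10	12954527	INTERGENIC	Increase	0.0062	0.97	0.80	0.83	0.0097
rs1025607	12	94884637	AMDHD1	Increase	0.011	1.12	0.26			0.0089
rs2347279	18	2528545	METTL4	Decrease	0.097	1.01	0.91	0.83	0.0025
rs1878553	18	2560155	NDC80	Decrease	0.030	1.03	0.83	0.83	0.0028
rs4803481	19	46758396	INTERGENIC	Decrease	0.055	0.97	0.81			0.0043
rs2302188	19	46777713	CEACAM21	Decrease	0.090	0.97	0.77	0.85	0.0075
"""


def replication_screen_example() -> pd.DataFrame:
    """The eight-row candidate screen table as a DataFrame."""
    return pd.read_csv(io.StringIO(_TABLE), sep="\t")


def screen_frames_from_example() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(candidates, screen1, screen2) frames for :func:`replication_screen`.

    Directions: screen1 from the reported risk effect (Increase/Decrease),
    screen2 and discovery from the odds ratio's side of 1. A missing
    discovery OR yields direction 0 (consistency then binds only between
    the two screens).
    """
    t = replication_screen_example()
    or_dir = lambda x: 0 if pd.isna(x) else (1 if x > 1 else -1)  # noqa: E731
    candidates = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "direction": t["discovery_or"].map(or_dir).astype(int),
        }
    )
    screen1 = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "p": t["screen1_p"],
            "direction": np.where(t["screen1_effect"] == "Increase", 1, -1),
        }
    )
    screen2 = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "p": t["screen2_p"],
            "direction": t["screen2_or"].map(or_dir).astype(int),
        }
    )
    return candidates, screen1, screen2
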