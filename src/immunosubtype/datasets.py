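"""Small published worked examples used as fixtures and regression anchors."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["scissor_labeling_example", "mutation_contingency_example"]


def scissor_labeling_example() -> pd.DataFrame:
    """Scissor cell counts for a published 16-sample AML single-cell cohort.

    Columns: ``total`` (detected cells), ``n_plus`` (Scissor+ cells) and
    ``n_minus`` (Scissor- cells) per sample; one sample has no reported
    Scissor+ count (NaN).  Feeding these counts to
    :func:`immunosubtype.scissor.label_samples` reproduces the published
    proportions, log2 fold changes and G1-/G2-featured/Neither labels.
    """
    rows = [
        ("AML870", 342, 71, 3),
        ("AML419A", 1057, 333, 49),
        ("AML556", 2270, 716, 151),
        ("AML328", 1070, 177, 57),
        ("AML921A", 3727, 867, 281),
        ("AML916", 929, 2, 356),
        ("AML707B", 1507, 12, 636),
        ("AML1012", 1040, 40, 297),
        ("AML420B", 476, 17, 115),
        ("AML329", 468, 95, 78),
        ("AML475", 372, 27, 33),
        ("AML722B", 78, 4, 5),
        ("AML371", 750, 121, 160),
        ("AML210A", 730, 76, 113),
        ("AML314", 162, 2, 6),
        ("AML997", 80, np.nan, 4),
    ]
    return pd.DataFrame(
        [(t, p, m) for _, t, p, m in rows],
        index=[s for s, *_ in rows],
        columns=["total", "n_plus", "n_minus"],
    )


def mutation_contingency_example() -> pd.DataFrame:
    """Published mutated/wild-type counts for FLT3, DNMT3A and NPM1 in two
    immune subgroups of two AML cohorts (mutated, wild-type per group)."""
    rows = [
        ("TCGA", "FLT3", 27, 44, 17, 78),
        ("TCGA", "DNMT3A", 24, 47, 17, 78),
        ("TCGA", "NPM1", 21, 50, 6, 89),
        ("BeatAML", "FLT3", 58, 156, 9, 32),
        ("BeatAML", "DNMT3A", 31, 56, 2, 22),
        ("BeatAML", "NPM1", 65, 149, 10, 31),
    ]
    return pd.DataFrame(rows, columns=[
        "cohort", "gene", "g1_mut", "g1_wt", "g2_mut", "g2_wt"])
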