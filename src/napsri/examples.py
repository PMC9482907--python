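"""Bundled worked example: cross-system annotation of nematode-extract features.

A small published-style case study used in the documentation and tests:
features detected in a Caenorhabditis elegans extract on a third LC-MS
system ("system 3": HPLC-format column in a UHPLC pump), with reference RT
and RI values from two library systems -- system 1 (UHPLC, different
column format) and system 2 (HPLC, same column as system 3 but different
pump hardware, extra-column volume and gradient dwell volume).  RTs differ
strongly across systems; RIs agree to a few index units, which is what
makes RI-based annotation portable.

The hydroxybenzoate feature (m/z 139.0389) is the classic isomer case: the
three C7H6O3 isomers (4-hydroxybenzoic acid, 3-hydroxybenzoic acid,
salicylic acid) are indistinguishable by accurate mass, but only
4-hydroxybenzoic acid matches within 10 RI units.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "case_study_features",
    "case_study_library",
    "isomer_feature",
    "isomer_library",
]


def case_study_features() -> pd.DataFrame:
    """Positive-mode features observed on system 3 (m/z, RT min, RI)."""
    rows = [
        ("trp", 205.0970, 5.03, 472, "pos"),
        ("rbf", 377.1459, 9.69, 586, "pos"),
        ("nap", 208.0967, 11.26, 634, "pos"),
        ("hba", 139.0389, 6.51, 513, "pos"),
    ]
    return pd.DataFrame(rows, columns=["feature_id", "mz", "rt_min", "ri", "polarity"])


def case_study_library() -> pd.DataFrame:
    """Reference RT/RI values for the case-study compounds on systems 1 and 2."""
    rows = [
        # compound, formula, adduct, polarity, (rt, ri) on system 1, (rt, ri) on system 2
        ("Tryptophan", "C11H12N2O2", "[M+H]+", "pos", 2.71, 474, 5.29, 475),
        ("Riboflavin", "C17H20N4O6", "[M+H]+", "pos", 4.66, 582, 12.31, 595),
        ("N-Acetylphenylalanine", "C11H13NO3", "[M+H]+", "pos", 5.38, 633, 13.83, 643),
        ("4-Hydroxybenzoic acid", "C7H6O3", "[M+H]+", "pos", 3.40, 511, 6.85, 521),
        ("3-Hydroxybenzoic acid", "C7H6O3", "[M+H]+", "pos", 4.30, 561, 9.54, 564),
        ("Salicylic acid", "C7H6O3", "[M+H]+", "pos", 4.30, 561, 9.54, 564),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "formula",
            "adduct",
            "polarity",
            "rt_sys1",
            "ri_sys1",
            "rt_sys2",
            "ri_sys2",
        ],
    )


def isomer_feature() -> pd.DataFrame:
    """The hydroxybenzoate feature: one m/z, three isobaric candidates."""
    feats = case_study_features()
    return feats[feats["feature_id"] == "hba"].reset_index(drop=True)


def isomer_library(system: int = 1) -> pd.DataFrame:
    """Mini-library of the three C7H6O3 isomers with RIs from one system."""
    lib = case_study_library()
    lib = lib[lib["formula"] == "C7H6O3"].reset_index(drop=True)
    out = lib[["compound_id", "formula", "adduct", "polarity"]].copy()
    out["mean_ri"] = lib[f"ri_sys{system}"].astype(float)
    out["mean_rt_min"] = lib[f"rt_sys{system}"].astype(float)
    return out
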