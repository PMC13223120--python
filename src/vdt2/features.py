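"""Canonical feature and column vocabulary shared across the package.

The 14 acoustic measures are the standard Praat-convention sustained-vowel
set: fundamental-frequency statistics, intensity statistics, the
harmonic-to-noise ratio, four jitter variants (period perturbation) and five
shimmer variants (amplitude perturbation).
"""

from __future__ import annotations

#: The 14 acoustic features, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "meanF0",
    "stdevF0",
    "meanInten",
    "stdevInten",
    "HNR",
    "localShimmer",
    "localdbShimmer",
    "apq3Shimmer",
    "apq5Shimmer",
    "apq11Shimmer",
    "localJitter",
    "localabsJitter",
    "rapJitter",
    "ppq5Jitter",
)

#: Metadata columns preceding the features in every cohort table.
META_COLUMNS: tuple[str, ...] = ("subject", "sex", "group", "vowel", "repetition")

#: The six Mandarin lingual vowels recorded per subject.
VOWELS: tuple[str, ...] = ("a", "o", "e", "i", "u", "ü")

#: Group labels. T2DM is the positive (disease) class throughout.
GROUP_T2DM = "T2DM"
GROUP_CONTROL = "ND"
GROUPS: tuple[str, ...] = (GROUP_T2DM, GROUP_CONTROL)


def canonical_feature_order(names) -> list[str]:
    """Sort a collection of feature names into canonical column order.

    Raises ``ValueError`` for names outside the 14-feature vocabulary.
    """
    names = list(names)
    unknown = sorted(set(names) - set(FEATURE_NAMES))
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    return [f for f in FEATURE_NAMES if f in set(names)]
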