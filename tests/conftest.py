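import numpy as np
import pytest

from vdt2 import acoustic, synth


@pytest.fixture(scope="session")
def reference_stats():
    return synth.reference_group_stats()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at the study composition (seed 42)."""
    return synth.sample_cohort(synth.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def perturbed_vowel():
    """A 4 s clean vowel with 2% jitter and 2% shimmer, its extracted
    features, and the ground-truth perturbation measures.

    Session-scoped: full-rate extraction is the most expensive operation in
    the suite and several tests share this signal.
    """
    spec = synth.VowelSynthSpec(
        f0_hz=155.3, jitter_frac=0.02, shimmer_frac=0.02,
        hnr_db=np.inf, duration_s=4.0, seed=3,
    )
    res = synth.synth_vowel(spec)
    w = acoustic.Waveform(res.samples, res.rate)
    feats = acoustic.extract_features(w)
    gt = acoustic.PeriodSequence(res.boundaries, res.periods, res.amplitudes)
    oracle = {**acoustic.jitter_metrics(gt), **acoustic.shimmer_metrics(gt)}
    return spec, res, feats, oracle
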