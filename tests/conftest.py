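import numpy as np
import pytest

from bimodalffr.preprocess import EpochSet
from bimodalffr.stimuli import DEFAULT_VOWELS, synth_vowel

RATE_EEG = 10_000.0
N_EPOCH = 5500  # [-50, 500) ms at 10 kHz


@pytest.fixture(scope="session")
def vowel_tokens():
    """The three default vowel tokens at 44.1 kHz (synthesized once)."""
    return {spec.label: synth_vowel(spec) for spec in DEFAULT_VOWELS}


def make_sine_epochs(
    n_trials: int,
    freq: float = 130.0,
    kappa: float = np.inf,
    amp: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    n_samples: int = N_EPOCH,
    rate: float = RATE_EEG,
    alternate_polarity: bool = True,
    flip_with_polarity: bool = False,
) -> EpochSet:
    """Trials = amp·sin(2π f t + φ) + white noise, φ ~ von Mises(0, κ).

    With ``flip_with_polarity`` the sinusoid's mean phase shifts by π for
    polarity-B trials (a TFS-like component).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    if np.isinf(kappa):
        ph = np.zeros(n_trials)
    elif kappa == 0:
        ph = rng.uniform(0, 2 * np.pi, n_trials)
    else:
        ph = rng.vonmises(0.0, kappa, n_trials)
    if alternate_polarity:
        pol = np.array(["A", "B"] * (n_trials // 2 + 1))[:n_trials]
    else:
        pol = np.array(["A"] * n_trials)
    if flip_with_polarity:
        ph = ph + np.pi * (pol == "B")
    trials = amp * np.sin(2 * np.pi * freq * t[None, :] + ph[:, None])
    if noise > 0:
        trials = trials + noise * rng.standard_normal((n_trials, n_samples))
    return EpochSet(trials, pol, np.zeros(n_trials, bool), rate)
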