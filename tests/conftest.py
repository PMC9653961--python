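import numpy as np
import pytest

from tonemg import ContourSpec, make_contour, synthesize_voice


def oracle_turn_count(x, threshold=100.0):
    """Brute-force turns oracle, independent of the production scan.

    Dynamic programming over raw samples: the longest subsequence whose
    consecutive steps alternate in sign and each reach ``threshold``; its
    interior elements are exactly the points with a qualifying excursion on
    both sides, so the turn count is max(0, length - 2).
    """
    x = list(map(float, x))
    n = len(x)
    up = [1] * n  # longest qualifying subsequence ending at i with an up-step
    dn = [1] * n
    for i in range(n):
        for j in range(i):
            if x[i] - x[j] >= threshold and dn[j] + 1 > up[i]:
                up[i] = dn[j] + 1
            if x[j] - x[i] >= threshold and up[j] + 1 > dn[i]:
                dn[i] = up[j] + 1
    best = max(max(up), max(dn)) if n else 0
    return max(0, best - 2)


def triangle_wave(freq, fs, duration=1.0, amplitude=100.0, include_endpoint=True):
    """Symmetric triangle through zero at t=0, peak-to-peak 2*amplitude."""
    n = int(round(duration * fs)) + (1 if include_endpoint else 0)
    t = np.arange(n) / fs
    phase = (t * freq) % 1.0
    tri = np.where(phase < 0.25, 4 * phase,
                   np.where(phase < 0.75, 2 - 4 * phase, 4 * phase - 4))
    return amplitude * tri


TONE_SPECS = {
    1: ContourSpec(1, 220.0, 220.0, 0.82),
    2: ContourSpec(2, 204.0, 244.0, 0.84),
    3: ContourSpec(3, 205.0, 189.0, 0.71, f0_min=170.0),
    4: ContourSpec(4, 254.0, 186.0, 0.45),
}


@pytest.fixture(scope="session")
def tone_specs():
    return TONE_SPECS


@pytest.fixture(scope="session")
def clean_voices():
    """Noiseless 5-harmonic synthetic voices for all four tones (fs 16 kHz)."""
    out = {}
    for tone, spec in TONE_SPECS.items():
        contour = make_contour(spec)
        rec, truth = synthesize_voice(contour, fs=16000.0, n_harmonics=5,
                                      noise_rms=0.0, seed=0, tone=tone)
        out[tone] = (spec, rec, truth)
    return out
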