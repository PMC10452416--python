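import numpy as np
import pytest

from mciscreen.cohort import EEGRecording
from mciscreen.simulate import EffectConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A tiny but complete synthetic cohort (written once per session)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = EffectConfig(
        n_mci=5, n_hc=5, seed=11, eeg_rest_s=12.0, eeg_task_s=12.0,
        speech_total_s_hc=5.0,
    )
    manifest = generate_cohort(cfg, out)
    return cfg, manifest, out


def sinusoid_recording(freq_hz: float, amplitude: float = 1.0, fs: float = 256.0,
                       duration_s: float = 8.0, state: str = "task") -> EEGRecording:
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(samples=np.tile(x, (4, 1)), fs=fs, state=state)
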