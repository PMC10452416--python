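"""Generate a small synthetic screening cohort and inspect what was planted.

Writes EEG CSVs, speech WAVs, transcripts, timing tables and a manifest
for 4 MCI + 4 HC participants, then prints one participant's planted
ground truth from the sidecar file.
"""

import tempfile

from mciscreen.simulate import EffectConfig, generate_cohort, load_truth

with tempfile.TemporaryDirectory() as out:
    cfg = EffectConfig(n_mci=4, n_hc=4, seed=7, eeg_rest_s=8.0, eeg_task_s=8.0,
                       speech_total_s_hc=5.0)
    manifest = generate_cohort(cfg, out)
    print(f"participants: {len(manifest.participants)}  tasks: {manifest.tasks}")
    print(f"complete cells: {len(manifest.complete_cells())}")

    p = manifest.participants[0]
    truth = load_truth(out, p.id)
    task1 = truth["tasks"]["task1"]
    print(f"\n{p.id} ({p.group}, MoCA {p.moca}, MMSE {p.mmse}):")
    print(f"  planted theta power, TP9 task state: "
          f"{task1['eeg_task_band_powers']['TP9']['theta']:.2f} uV^2")
    print(f"  planted speech time: {task1['speech_layout']['total_speech_s']:.2f} s "
          f"over {len(task1['speech_layout']['speech'])} bursts")
    print(f"  planted F0: {task1['speech_layout']['f0']:.1f} Hz; "
          f"characters: {task1['n_chars']}; "
          f"test time: {task1['total_test_time']:.1f} s")
print("MCI participants get boosted task-state theta, less speech, fewer")
print("characters and longer test times than controls.")
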