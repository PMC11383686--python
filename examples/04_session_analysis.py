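"""Full spike/LFP analysis chain on a synthetic session.

Generates a trial-structured session (memory IN/OUT conditions, 4
orientations x 3 contrasts + zero contrast, ~1 s delay with a beta
oscillation stronger for IN), then runs the analysis chain: multitaper
delay-period spectra with beta band power, spike-phase locking, the
spike-triggered average LFP, and the beta-band phase/rate mutual
information.
"""

from phasecode.pipeline import RunConfig, run_session_analysis

cfg = RunConfig(mode="session", out_dir="results/example_session", seed=7,
                session={"n_trials": 10})
res = run_session_analysis(cfg)

print(res["spl_sta"][["condition", "beta_power_raw", "peak_freq", "spl",
                      "sta_slope"]].to_string(index=False))
print()
print(res["mi_summary"].to_string(index=False))
print(f"\nsubsampled peak-frequency vs rate correlation (IN): "
      f"r = {res['subsample_r']:.2f}")
print("Expected pattern: the IN condition shows higher raw beta power, "
      "stronger spike-phase locking, and more beta-band phase MI than "
      "OUT, while rate MI is similar - the WM signature is in spike "
      "timing, not rate.")
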