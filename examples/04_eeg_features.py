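"""Generate synthetic feedback-locked EEG and quantify its components.

Builds epochs for one simulated session, applies the measurement chain
(artifact rejection, baseline, FRN peak-to-peak, P3 mean amplitude,
Morlet theta/delta power) and prints the cell means by valence and
expectancy.
"""

from twostep_eeg import REFERENCE_PARAMS, TaskConfig, simulate_agent
from twostep_eeg.eeg_sim import generate_epochs, inject_artifacts
from twostep_eeg.features import (baseline_correct, reject_artifacts,
                                  trial_features)

trials, _ = simulate_agent(REFERENCE_PARAMS, TaskConfig(n_blocks=2),
                           seed=4)
epochs, ledger = generate_epochs(trials, seed=4)
epochs = inject_artifacts(epochs, fraction=0.05, seed=4)
print(f"generated {epochs.n_trials} epochs "
      f"({epochs.trial_meta['artifact'].sum()} with injected artifacts)")

clean = reject_artifacts(epochs, threshold=300.0)
print(f"epochs surviving the +/-300 uV criterion: {clean.n_trials}")
feats = trial_features(baseline_correct(clean))

cells = feats.groupby(["valence", "expectancy"])[
    ["frn_p2p", "p3_mean", "theta_db", "delta_db"]].mean().round(2)
print("\ncomponent means by outcome cell (uV for FRN/P3, dB for bands):")
print(cells.to_string())
print("\n-> FRN is more negative and theta power higher for unexpected "
      "outcomes;\n   the P3/delta expectancy effects are configured to "
      "arise only under the\n   predictable internal model (split by "
      "condition to see the dissociation).")
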