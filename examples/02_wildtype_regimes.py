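"""Wild-type map development under three compensation regimes.

Runs reduced-length versions of the named scenarios (full-length runs are
what the tests and the acceptance script use) and prints the order
metrics: rank correlation (1 = perfectly ordered), RMS deviation from the
identity map and mean signed shift (negative = rostral displacement).
"""

import retinotopy as rt

STEPS = 2_000_000   # reduced from the scenarios' defaults for a quick demo

for name in ("fig2_strong_no_counter", "fig3_weak_no_counter",
             "fig4_weak_counter"):
    report = rt.run_scenario(name, seed=0, n_steps=STEPS)
    m = report.metrics
    print(f"{name}:")
    print(f"  rank correlation {m['rank_correlation']:.3f}, "
          f"rms from identity {m['rms_from_identity']:.3f}, "
          f"mean shift {m['mean_signed_shift']:+.3f}")

print("\nweak compensation alone leaves a rostral shift; adding"
      " countergradients (fig4) pulls the map back toward the identity.")
print("strong compensation (fig2) orders the map diffusively and is still"
      " mid-ordering at this demo length; its scenario default"
      " (40M steps, run by the tests and the acceptance script) completes"
      " the ordering.")
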