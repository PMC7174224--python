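"""Benchmark the 22-classifier suite on a synthetic three-class dataset.

Builds a 15/15/15 image set, extracts the 120 features per sample, runs
fivefold stratified cross-validation repeated 3 times for every preset,
and prints the ranked accuracy table plus the ANOVA/Duncan comparison.
(The full protocol uses 10 repetitions; 3 keeps this example quick.)
"""

from saffronvision.classify import CvConfig
from saffronvision.pipeline import RunConfig, run_experiment
from saffronvision.preprocess import PreprocessParams

config = RunConfig(
    counts={"Pushal": 15, "Negin": 15, "Sargol": 15},
    preprocess=PreprocessParams(min_component_area=64, structuring_radius=2),
    cv=CvConfig(k=5, repetitions=3, seed=7),
    seed=7,
)
bundle = run_experiment(config)

print("ranked mean accuracy over 3 repetitions of fivefold CV (percent):")
print(bundle["summary"].to_string(index=False))
print()
an = bundle["anova"]
print(f"ANOVA across classifiers: F({an['df_between']}, {an['df_within']}) "
      f"= {an['F']:.2f}, p = {an['p']:.3g}")
if bundle["duncan"] is not None:
    print("Duncan homogeneous subsets (classifiers sharing a letter do not")
    print("differ significantly at alpha = 0.05):")
    print(bundle["duncan"].as_frame().to_string())
print()
print("High-ranked presets separate the grades using the composition and")
print("texture contrasts the generator builds in; a letter shared across")
print("rows means those classifiers are statistically indistinguishable.")
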