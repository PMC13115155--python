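"""Generate the default synthetic storage study and write it to disk.

36 frozen-pizza scenes (18 per storage temperature, 0-200 days) with
ground-truth masks, simulated saturation trajectories and Bernoulli
acceptability labels.  Output: results/study/.
"""

import warnings

from saucelife import imgen
from saucelife.io import write_study

SEED = 42

if __name__ == "__main__":
    warnings.simplefilter("ignore")
    spec = imgen.default_study_spec(seed=SEED)
    dataset = imgen.generate_study(spec)
    write_study(dataset, "results/study")
    by_group = dataset.records.groupby(["temperature_c", "label"]).size()
    print(f"wrote {len(dataset.records)} samples to results/study")
    print("samples per temperature x acceptability group:")
    print(by_group.to_string())
    print(
        "saturation range (targets): "
        f"{dataset.records['true_saturation'].min():.1f} - "
        f"{dataset.records['true_saturation'].max():.1f}"
    )
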