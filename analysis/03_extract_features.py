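"""Compute the 36-feature color-moment descriptor for every segmented sample.

Output: results/features.csv (one row per sample, metadata + 36 features).
"""

import pandas as pd

from saucelife import colorfeat
from saucelife.io import read_image, read_mask

if __name__ == "__main__":
    records = pd.read_csv("results/study/records.csv")
    images = [read_image(f"results/study/{p}") for p in records["image_path"]]
    masks = [read_mask(f"results/masks/{s}_sauce.png") for s in records["sample_id"]]
    table = colorfeat.features_table(images, masks, records)
    table.to_csv("results/features.csv", index=False)
    print(f"extracted {len(colorfeat.FEATURE_NAMES)} features for {len(table)} samples")
    print(
        "HSV_S_mean range: "
        f"{table['HSV_S_mean'].min():.1f} - {table['HSV_S_mean'].max():.1f}"
    )
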