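"""Screen features by Pearson correlation with storage time, per group.

Correlations are computed within each (temperature x acceptability)
group and features ranked by mean signed r across groups.  Output:
results/screen/.
"""

from pathlib import Path

import pandas as pd

from saucelife import screen

if __name__ == "__main__":
    table = pd.read_csv("results/features.csv")
    groups = screen.grouped_correlations(table)
    Path("results/screen").mkdir(parents=True, exist_ok=True)
    for (temp, lab), df in groups.items():
        df.to_csv(f"results/screen/correlations_T{temp:g}_class{lab}.csv", index=False)
    ranking = screen.rank_features(groups)
    ranking.to_csv("results/screen/ranking.csv", index=False)
    print(f"{len(groups)} populated groups")
    print("top five features by mean correlation with storage time:")
    print(ranking.head(5).to_string(index=False))
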