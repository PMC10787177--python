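"""CompPASS statistics and nine-feature vectors for candidate pairs.

Reads results/counts.tsv, writes results/compass_stats.tsv and
results/features.tsv.
"""

from pathlib import Path

import pandas as pd

from altppi.compass import build_features, compute_stats
from altppi.counts import SpectralCountMatrix

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = pd.read_csv(ROOT / "study" / "design.tsv", sep="\t")
    matrix = SpectralCountMatrix(pd.read_csv(ROOT / "counts.tsv", sep="\t"), design)
    stats = compute_stats(matrix)
    stats.to_csv(ROOT / "compass_stats.tsv", sep="\t", index=False)
    features = build_features(stats, matrix, design)
    features.to_csv(ROOT / "features.tsv", sep="\t", index=False)
    top = stats.nlargest(3, "wd")[["bait_id", "prey", "x_avg", "z", "wd"]]
    print(f"scored {len(stats)} pairs; {len(features)} candidate feature vectors")
    print("highest WD-scores:\n", top.to_string(index=False))


if __name__ == "__main__":
    main()
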