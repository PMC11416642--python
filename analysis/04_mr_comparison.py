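"""Compare the five MR estimators: calibration and catalog triplets.

First contrasts the fixed and multiplicative-random IVW models under a
heterogeneous null (per-instrument slopes spread around zero), the
mechanism by which standard IVW-MR manufactures false positives. Then
fits all five estimators to the catalog's multi-signal triplets. Writes
results/mr_null_calibration.tsv and results/mr.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, build_catalog

from colocbench import MRInput, mr_ivw
from colocbench.pipeline import RunConfig, run_end_to_end


def null_calibration(seed: int = 17, n_loci: int = 400) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    counts = {"fixed": 0, "random": 0}
    for _ in range(n_loci):
        k = int(rng.integers(2, 6))
        bx = rng.uniform(0.3, 1.0, k)
        by = rng.normal(0.0, 0.5, k) * bx + rng.normal(0, 0.02, k)
        inp = MRInput(bx, np.full(k, 0.01), by, np.full(k, 0.02))
        counts["fixed"] += mr_ivw(inp, "delta", "fixed").significant
        counts["random"] += mr_ivw(inp, "delta", "random").significant
    return pd.DataFrame(
        [{"model": m, "false_positive_rate": c / n_loci, "n_loci": n_loci}
         for m, c in counts.items()]
    )


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    calib = null_calibration()
    calib.to_csv(RESULTS / "mr_null_calibration.tsv", sep="\t", index=False)
    print("heterogeneous-null 80%-interval false-positive rates:")
    for row in calib.itertuples():
        print(f"  {row.model:6s} model: {row.false_positive_rate:.1%}")

    res = run_end_to_end(build_catalog(), RunConfig())
    mr = pd.DataFrame(res.mr_rows)
    mr.to_csv(RESULTS / "mr.tsv", sep="\t", index=False)
    if len(mr):
        print(f"\n{mr.groupby('method').size().iloc[0]} multi-signal triplets "
              f"fitted by each estimator:")
        mr["sig_fp"] = mr.significant & ~mr.is_tp
        summary = mr.groupby("method").agg(
            triplets=("significant", "size"),
            significant=("significant", "sum"),
            significant_false_positives=("sig_fp", "sum"),
        )
        print(summary.to_string())


if __name__ == "__main__":
    main()
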