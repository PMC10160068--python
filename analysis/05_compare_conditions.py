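#!/usr/bin/env python
"""Compare the disinfected and non-disinfected communities: per-sample
quantities with Student's t-tests, Bray-Curtis PCoA, and Mantel tests of the
community structure against the environmental covariates.

Reads results/community/ and results/abundance/, writes results/stats/.
"""

from pathlib import Path

import pandas as pd

from vdp.io import read_table
from vdp.stats import (
    benjamini_hochberg,
    bray_curtis_matrix,
    euclidean_matrix,
    mantel,
    pcoa,
    pearson,
    t_test,
)

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    out = BASE / "stats"
    out.mkdir(parents=True, exist_ok=True)
    community = BASE / "community"

    tpm = pd.read_csv(BASE / "abundance" / "tpm.tsv", sep="\t", index_col=0)
    samples = read_table(community / "samples.tsv").set_index("sample_id")
    samples = samples.loc[list(tpm.columns)]
    dis = samples["condition"] == "disinfected"

    carriers = pd.read_csv(
        BASE / "defense" / "carrier_fraction.tsv", sep="\t", index_col=0
    )["carrier_fraction"]
    burden = pd.read_csv(
        BASE / "defense" / "spacer_burden.tsv", sep="\t", index_col=0
    )["M"]
    diversity = pd.read_csv(
        BASE / "abundance" / "diversity.tsv", sep="\t", index_col=0
    )["shannon"]

    rows = []
    for name, series in (
        ("defense_carrier_share", carriers),
        ("spacer_burden_M", burden),
        ("shannon", diversity),
    ):
        res = t_test(series[dis.values], series[~dis.values])
        rows.append({"test": f"t:{name}", "statistic": res.statistic,
                     "p_value": res.p_value})

    bc = bray_curtis_matrix(tpm)
    coords, _evals, var_exp = pcoa(bc, k=2)
    pd.DataFrame(
        {"sample_id": bc.ids, "PCo1": coords[:, 0], "PCo2": coords[:, 1],
         "condition": samples["condition"].to_numpy()}
    ).to_csv(out / "pcoa.tsv", sep="\t", index=False)

    for covariate in ("chlorine", "phosphate"):
        env = euclidean_matrix(samples[covariate].to_numpy(), bc.ids)
        res = mantel(bc, env, n_perm=999, seed=SEED)
        rows.append({"test": f"mantel:{covariate}", "statistic": res.statistic,
                     "p_value": res.p_value})

    res = pearson(samples["chlorine"].to_numpy(), carriers.to_numpy())
    rows.append({"test": "pearson:chlorine~carrier_share",
                 "statistic": res.statistic, "p_value": res.p_value})

    stats = pd.DataFrame(rows)
    stats["q_value"] = benjamini_hochberg(stats["p_value"])
    stats.to_csv(out / "tests.tsv", sep="\t", index=False)

    print("condition comparison (statistic, p, BH q):")
    for row in stats.itertuples(index=False):
        print(f"  {row.test}: stat={row.statistic:+.3f} "
              f"p={row.p_value:.3g} q={row.q_value:.3g}")
    print(f"PCoA: PCo1 {100 * var_exp[0]:.1f}%, PCo2 {100 * var_exp[1]:.1f}% "
          "of positive-eigenvalue variance")


if __name__ == "__main__":
    main()
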