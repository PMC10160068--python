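#!/usr/bin/env python
"""Generate the synthetic two-condition drinking-water community.

Writes the community (contigs, alignments, feature tables, planted truth)
under results/community/ for the downstream analysis scripts.
"""

from pathlib import Path

from vdp.synth import (
    SyntheticConfig,
    generate_community,
    simulate_alignments,
    write_community,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "community"


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    contigs, features, truth = generate_community(cfg)
    alignments = simulate_alignments(contigs, truth, cfg)
    write_community(contigs, features, truth, alignments, OUT)

    n_prok = sum(c.category == "prokaryotic" for c in contigs)
    n_viral = len(contigs) - n_prok
    print(f"community written to {OUT}")
    print(f"  {n_prok} prokaryotic contigs in {cfg.n_genera} genera")
    print(f"  {n_viral} viral contigs ({len(features['prophages'])} embedded "
          "as prophages)")
    print(f"  {len(truth.true_arrays)} planted CRISPR arrays, "
          f"{len(truth.true_host_links)} planted host links")
    print(f"  {len(truth.sample_conditions)} samples "
          f"({cfg.n_samples_per_condition} per condition), "
          f"{cfg.reads_per_sample} reads each")


if __name__ == "__main__":
    main()
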