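#!/usr/bin/env python
"""Simulate the study's input data: two-sample GWAS summary statistics for a
small exposure x outcome grid with known causal structure.

Two synthetic cardiovascular risk factors stand in for the published GWAS
downloads: one with a real causal effect on the ECG trait (0.2 SD per SD,
blood-pressure-style, 55 instruments from a GWAS of 201,529) and one null
(0.0, 79 instruments, 339,224 — body-mass-index scale).  Each is paired with
one outcome table at the QRS-trait GWAS scale (n = 73,518).  The causal
exposure's outcome tables get allele corruption (20% effect/other swaps,
10% strand complements, 5% palindromes) so the downstream harmonization is
exercised on realistic mess.

Writes TSV tables plus truth/corruption JSON under results/data/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from mrtools.sumstats import write_association_table
from mrtools.synthetic import SyntheticConfig, corrupt_alleles, generate_two_sample

ARMS = {
    # name: (n_variants, causal effect, exposure GWAS n, corruption?)
    "sbp_like": dict(n_variants=55, causal_effect=0.2, n_exposure=201_529, corrupt=True),
    "bmi_like": dict(n_variants=79, causal_effect=0.0, n_exposure=339_224, corrupt=False),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for i, (name, arm) in enumerate(ARMS.items()):
        cfg = SyntheticConfig(
            seed=args.seed + 1000 * i,
            n_variants=arm["n_variants"],
            causal_effect=arm["causal_effect"],
            n_exposure=arm["n_exposure"],
            flip_fraction=0.2 if arm["corrupt"] else 0.0,
            complement_fraction=0.1 if arm["corrupt"] else 0.0,
            palindrome_fraction=0.05 if arm["corrupt"] else 0.0,
        )
        exposure, outcome, truth = generate_two_sample(cfg)
        exposure, outcome, log = corrupt_alleles(exposure, outcome, truth, cfg)
        write_association_table(exposure, args.out_dir / f"{name}_exposure.tsv")
        write_association_table(outcome, args.out_dir / f"{name}_outcome.tsv")
        (args.out_dir / f"{name}_truth.json").write_text(
            json.dumps(
                {
                    "causal_effect": truth.causal_effect,
                    "gamma": truth.gamma.tolist(),
                    "alpha": truth.alpha.tolist(),
                    "corruption_log": log,
                    "config": dataclasses.asdict(cfg),
                },
                indent=2,
            )
            + "\n"
        )
        print(
            f"{name}: {len(exposure)} instruments (true effect {arm['causal_effect']}), "
            f"{len(log)} outcome rows corrupted -> {args.out_dir}/{name}_*.tsv"
        )


if __name__ == "__main__":
    main()
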