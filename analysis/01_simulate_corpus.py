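#!/usr/bin/env python
"""Generate the synthetic study corpora.

Writes two corpora under results/corpus/:
  * cohort.jsonl   — sampled from the default study-condition margins
                     (150 patients, median 2 / max 11 posts each)
  * planted.jsonl  — deterministic mode planting the packaged occurrence
                     vector (the corpus used for closed-world validation)
plus their ground-truth files.
"""

import argparse
from pathlib import Path

from hrqolsm.corpus import write_corpus
from hrqolsm.simulate import GeneratorConfig, generate_corpus
from hrqolsm.taxonomy import load_taxonomy, occurrence_vector

def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/corpus"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    subdomains, _ = load_taxonomy()

    sampled_cfg = GeneratorConfig(seed=args.seed)
    posts, truth = generate_corpus(sampled_cfg, subdomains)
    write_corpus(posts, args.out / "cohort.jsonl")
    truth.save(args.out / "cohort_truth.json")
    print(f"sampled cohort: {len(posts)} posts, {len(truth.patients)} patients, "
          f"{len(truth.duplicates)} duplicates, {len(truth.decoys)} decoys")

    planted_cfg = GeneratorConfig(
        occurrence_vector=occurrence_vector(subdomains),
        deterministic_margins=True,
        seed=args.seed,
    )
    posts, truth = generate_corpus(planted_cfg, subdomains)
    write_corpus(posts, args.out / "planted.jsonl")
    truth.save(args.out / "planted_truth.json")
    print(f"planted cohort: {len(posts)} posts carrying the full 42-subdomain "
          f"occurrence vector ({sum(len(v) for v in truth.mentions.values())} mentions)")

if __name__ == "__main__":
    main()
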