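#!/usr/bin/env python
"""Build the analysis corpus from the planted raw posts.

Applies the corpus funnel (keyword inclusion, same-user dedup,
deidentification) and exports the document-term matrix; prints the funnel
counts so the attrition at each stage is visible.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

from hrqolsm.corpus import (
    build_dtm,
    deduplicate,
    deidentify,
    filter_posts,
    read_corpus,
    tokenize_posts,
    write_corpus,
)

def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in", dest="in_path", type=Path,
                        default=Path("results/corpus/planted.jsonl"))
    parser.add_argument("--out", type=Path, default=Path("results/built"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = read_corpus(args.in_path)
    kept, matched = filter_posts(raw)
    deduped, removals = deduplicate(kept)
    clean, n_redactions = [], 0
    for post in deduped:
        redacted, spans = deidentify(post.text)
        clean.append(replace(post, text=redacted))
        n_redactions += len(spans)
    write_corpus(clean, args.out / "posts.jsonl")
    (args.out / "matched_keywords.json").write_text(
        json.dumps(matched, indent=1, sort_keys=True))

    tokenized = tokenize_posts(clean, matched)
    dtm = build_dtm(tokenized)
    dtm.save(args.out)

    print(f"funnel: {len(raw)} raw -> {len(kept)} with ICI keyword -> "
          f"{len(deduped)} after removing {len(removals)} duplicates; "
          f"{n_redactions} PII spans redacted")
    print(f"document-term matrix: {dtm.matrix.shape[0]} posts x "
          f"{dtm.matrix.shape[1]} tokens ({dtm.weighting})")

if __name__ == "__main__":
    main()
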