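#!/usr/bin/env python
"""Sequence signatures of the putative piRNAs: length distribution,
positional nucleotide frequencies (1U/10A), and the 5'-overlap ping-pong
histogram with z-score and 2-fold call.

Reads the pipeline tables from results/pipeline/ and summarizes them;
writes results/signatures_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pipedir", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--out", type=Path, default=Path("results/signatures_summary.tsv"))
    args = ap.parse_args()

    lengths = pd.read_csv(args.pipedir / "length_distribution.tsv", sep="\t", comment="#")
    mode = int(lengths.loc[lengths["reads"].idxmax(), "length"])
    in_24_32 = lengths[(lengths.length >= 24) & (lengths.length <= 32)]["reads"].sum()
    share = in_24_32 / lengths["reads"].sum()

    freq5 = pd.read_csv(args.pipedir / "positional_freq_5p.tsv", sep="\t", comment="#",
                        index_col="position")
    rate_1u = freq5.loc[1, "T"]
    rate_10a = freq5.loc[10, "A"]

    pp = pd.read_csv(args.pipedir / "pingpong.tsv", sep="\t", comment="#")
    rows = [
        dict(quantity="length_mode_nt", value=mode),
        dict(quantity="share_24_32nt", value=round(share, 4)),
        dict(quantity="rate_1U", value=round(rate_1u, 4)),
        dict(quantity="rate_10A", value=round(rate_10a, 4)),
    ]
    for _, r in pp.iterrows():
        rows.append(dict(quantity=f"pingpong_z_{r['context']}", value=round(r["z"], 2)))
        rows.append(dict(quantity=f"pingpong_twofold_{r['context']}", value=bool(r["twofold"])))
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, sep="\t", index=False)

    print(f"length mode {mode} nt; {share:.1%} of mapped reads in 24-32 nt")
    print(f"1U rate {rate_1u:.1%}; 10A rate {rate_10a:.1%}")
    for _, r in pp.iterrows():
        print(f"ping-pong [{r['context']}]: z = {r['z']:.1f}, "
              f"2-fold rule {'passed' if r['twofold'] else 'failed'} "
              f"({r['n_pairs']:.0f} overlapping pairs)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
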