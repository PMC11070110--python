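#!/usr/bin/env python
"""Rank plasma-membrane receptors by capacity to drive the M1 program.

Searches the evidence-costed curated network for sign-consistent
minimum-cost paths from each candidate receptor to the phenotype panel
(pro: TNF, IL6, IL1B, IL12B up; anti: TGFBR2, ADORA3, FFAR4 down),
aggregates exp(-cost) path credits into composite scores, and writes
the rank-ordered list under results/ranking/.
"""

import argparse
from pathlib import Path

from mevrank import io as mio
from mevrank.fixtures import load_curated_network, load_curated_receptors
from mevrank.ranking import rank_receptors

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "ranking")
    parser.add_argument("--sign-mode", choices=["strict", "lenient"], default="strict")
    args = parser.parse_args()

    net = load_curated_network()
    scores = rank_receptors(net, load_curated_receptors(), mode=args.sign_mode)
    args.out.mkdir(parents=True, exist_ok=True)
    mio.write_ranking(scores, args.out / "ranking.tsv")
    mio.write_json(mio.ranking_report(scores), args.out / "ranking.json")

    print("receptor ranking (composite = pro - anti path credit):")
    for s in scores:
        best = min(s.paths, key=lambda p: p.total_cost) if s.paths else None
        route = " -> ".join(best.nodes) if best else "(no path)"
        print(f"  {s.rank}. {s.receptor:9s} composite {s.composite:+.5f}   best: {route}")
    print(f"wrote {args.out / 'ranking.tsv'}")


if __name__ == "__main__":
    main()
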