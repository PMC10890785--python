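#!/usr/bin/env python
"""Junction sequence context: 20-bp windows, PWMs, GT/AG consensus.

Extracts the 10 bp on each side of every donor (5') and acceptor (3')
breakpoint in gene-strand orientation, builds per-side position weight
matrices, and asks whether the canonical GT donor / AG acceptor
dinucleotides carry the maximal weights. Outputs land in results/motif/.
"""

import json
from pathlib import Path

from fusionatlas.fusion_classify import classify_all, filter_candidates, resolve_models
from fusionatlas.io_formats import read_annotation, read_fusion_table, read_genome
from fusionatlas.junction_motif import build_pwm, consensus_report, extract_junction_windows

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "motif"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    calls = filter_candidates(read_fusion_table(ROOT / "data" / "fusions.tsv"))
    models = resolve_models(read_annotation(ROOT / "data" / "annotation.gtf"))
    genome = read_genome(ROOT / "data" / "genome.fa")
    classified = classify_all(calls, models, genome)

    windows, dropped = extract_junction_windows(classified, genome)
    if dropped:
        print(f"dropped {dropped} windows at chromosome ends")

    report = {}
    for side in ("donor", "acceptor"):
        side_windows = [w for w in windows if w.side == side]
        pwm = build_pwm(side_windows)
        pwm.to_frame().to_csv(OUT / f"pwm_{side}.tsv", sep="\t")
        rep = consensus_report(pwm)
        report[side] = {"consensus": rep.consensus,
                        "donor_canonical": rep.donor_canonical,
                        "acceptor_canonical": rep.acceptor_canonical,
                        "n_sequences": pwm.n_sequences}
        print(f"{side}: n = {pwm.n_sequences}, consensus = {rep.consensus}")
    print(f"canonical GT at donor +1/+2: {report['donor']['donor_canonical']}; "
          f"canonical AG at acceptor -2/-1: {report['acceptor']['acceptor_canonical']}")
    with open(OUT / "consensus.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"wrote PWMs -> {OUT}")


if __name__ == "__main__":
    main()
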