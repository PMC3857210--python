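"""Generate the benchmark cohort used by the downstream analyses.

A connected 100-gene / 250-interaction network and a 182-vs-48 two-group
expression matrix with 8 up- and 8 down-regulated planted interactions
(1.5 log2 units per endpoint, noise sigma 0.3). Two variants are written:
the homogeneous cohort (every responder carries every signal) and the
heterogeneous one (only a quarter of responders carry each signal). The
full matrices live under scratch/ (regenerated on demand from the seed);
results/ receives the compact ground-truth and cohort summaries.
"""

import json
from pathlib import Path

from netcondense import simulate_cohort, write_cohort

SEED = 7
ROOT = Path(__file__).resolve().parents[1]

for tag, carrier_fraction in (("homogeneous", 1.0), ("heterogeneous", 0.25)):
    net, matrix, labels, truth = simulate_cohort(
        seed=SEED, carrier_fraction=carrier_fraction
    )
    cohort_dir = ROOT / "scratch" / f"cohort_{tag}"
    write_cohort(cohort_dir, net, matrix, labels, truth)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    truth.to_json(out / f"01_truth_{tag}.json")
    summary = {
        "seed": SEED,
        "carrier_fraction": carrier_fraction,
        "genes": net.n_nodes,
        "interactions": net.n_edges,
        "non_responders": truth.n_A,
        "responders": truth.n_B,
        "planted_up": sum(e.direction == "up" for e in truth.planted),
        "planted_down": sum(e.direction == "down" for e in truth.planted),
        "carriers_per_signal": len(truth.planted[0].carriers),
    }
    (out / f"01_cohort_{tag}.json").write_text(json.dumps(summary, indent=2))
    print(f"[{tag}] {summary['genes']} genes, {summary['interactions']} "
          f"interactions, {summary['carriers_per_signal']}/{truth.n_B} "
          f"responders carry each planted signal -> {cohort_dir}")
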