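"""Ancestral-range reconstruction on the simulated camouflaged invasion.

Reads the synthetic tree and region coding from results/sim/ (run
01_simulate_inputs.py first), fits the equal-rates Mk model, reconstructs
marginal ancestral regions, and calls invasions of the focal region; the
calls are compared with the planted truth.  Writes results/ancestry/.
"""

import json
from pathlib import Path

import pandas as pd

from melinvade.mk import call_invasions, fit_mk, marginal_ancestral_states
from melinvade.phylo import read_newick, read_regions_csv

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "ancestry"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    tree = read_newick(SIM / "tree.nwk")
    coding = read_regions_csv(SIM / "regions.csv")
    truth = json.loads((SIM / "truth.json").read_text())

    fit = fit_mk(tree, coding)
    anc = marginal_ancestral_states(tree, coding, fit)
    calls, clades = call_invasions(tree, coding, anc, "Africa", threshold=0.9)

    planted = set(truth["invasion_tips"])
    flagged = {c.tip_label for c in calls if c.flagged}
    rows = [{"node_id": nid, **{s: float(p) for s, p in zip(anc.states, v)}}
            for nid, v in anc.probs.items()]
    pd.DataFrame(rows).to_csv(OUT / "node_marginals.csv", index=False)
    with open(OUT / "invasion_calls.json", "w") as fh:
        json.dump({"q_hat": fit.q, "log_likelihood": fit.log_likelihood,
                   "clades": [vars(c) for c in clades],
                   "flagged_tips": sorted(flagged),
                   "planted_tips": sorted(planted),
                   "planted_recovered": any(set(c.tips) == planted
                                            for c in clades)},
                  fh, indent=2)

    print(f"fitted dispersal rate q = {fit.q:.4f} "
          f"(loglik {fit.log_likelihood:.3f})")
    print(f"{len(clades)} clade-level invasion call(s); "
          f"planted clade {sorted(planted)} "
          f"{'recovered' if any(set(c.tips) == planted for c in clades) else 'missed'}")
    print(f"flagged tips outside the planted clade: {sorted(flagged - planted)}"
          f" (these sit on genuine recent region shifts, which the method"
          f" cannot distinguish from plantings; recovery and false-positive"
          f" rates over 50 replicates are measured in the test suite)")
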