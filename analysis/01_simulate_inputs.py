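"""Generate the default synthetic input set used by the downstream drivers.

Writes a 200-tip Yule tree with two-region Mk evolution and one planted
5-tip camouflaged clade, a clonal-morph score table, and a hotspot
population grid with density-biased invasion sites, into results/sim/.
"""

from pathlib import Path

from melinvade.cli import run_simulate
from melinvade.synth import PlantedInvasion, RegionConfig, SimulationConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

if __name__ == "__main__":
    import logging
    logging.basicConfig(level=logging.INFO)
    cfg = SimulationConfig(
        seed=7,
        regions=RegionConfig(states=("Africa", "Asia"), q_true=0.1,
                             planted=PlantedInvasion(clade_size=5,
                                                     source="Asia",
                                                     focal="Africa")))
    run_simulate(cfg, OUT)
    print(f"synthetic inputs written to {OUT}")
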