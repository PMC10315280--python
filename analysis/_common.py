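"""Shared configuration for the numbered analysis drivers.

Every driver reads the synthetic study written by ``01_simulate_study.py``
under ``results/sim`` and writes its tables under ``results/``.
"""

from pathlib import Path

from divergescan.config import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

CONFIG = SimulationConfig(n_genes=150, seed=1)


def results_dir(name: str) -> Path:
    out = RESULTS / name
    out.mkdir(parents=True, exist_ok=True)
    return out
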