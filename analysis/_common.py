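"""Shared plumbing for the numbered analysis drivers.

Each driver regenerates the synthetic study deterministically from the
config written by ``01_simulate_city.py`` (results/data/config.txt), so
the large minute-level series never need to sit on disk between stages.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from schoolenv import SimConfig, generate_study
from schoolenv.synthetic import config_from_file

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=0, help="simulation seed (ignored if a config file exists)")
    return p


def load_study(seed: int):
    """Regenerate the study from the saved config, or from defaults."""
    cfg_path = DATA / "config.txt"
    cfg = config_from_file(cfg_path) if cfg_path.exists() else default_config(seed)
    return generate_study(cfg)
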