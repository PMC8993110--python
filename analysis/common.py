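"""Shared configuration for the numbered analysis drivers.

All drivers operate on the bundled three-city synthetic ensemble under
``results/run/`` so each stage can be rerun independently.
"""

from pathlib import Path

from citytrends import demo_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"
SEED = 0


def get_config():
    return demo_config(RUN_DIR, seed=SEED)
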