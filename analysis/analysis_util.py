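"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def say(msg: str) -> None:
    print(msg, flush=True)
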