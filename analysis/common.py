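"""Shared conditions for the numbered analysis drivers.

Every driver regenerates its inputs from these constants, so each script can
be run on its own and the whole sequence is reproducible from the seed.
"""

from pathlib import Path

from critstate.synth import SynthStateParams, generate_labeled_recording

SEED = 0
DURATION_S = 600.0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def labeled_recording(seed: int = SEED, duration: float = DURATION_S):
    """The study's synthetic stand-in recording (five cortical states)."""
    return generate_labeled_recording(SynthStateParams(), duration, seed)
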