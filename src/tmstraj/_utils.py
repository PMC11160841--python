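"""Small shared helpers: seeding, validation errors."""

from __future__ import annotations

import numpy as np

WEEKS = np.arange(7)  # modeled weeks 0..6
N_WEEKS = 7
SCORE_MIN, SCORE_MAX = 0.0, 27.0


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def child_seed(master_seed: int, stream: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from a master seed.

    Uses SeedSequence spawning keyed on a stable hash of the stream name so
    that every stochastic stage of a pipeline gets an independent stream.
    """
    tag = np.frombuffer(stream.encode(), dtype=np.uint8)
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *tag.tolist()])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
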