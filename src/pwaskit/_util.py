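"""Shared helpers: deterministic per-stage seeding and sequence utilities."""

from __future__ import annotations

import hashlib


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific RNG seed (< 2**31) from one master seed.

    All randomness in the package flows from a single integer seed; each
    stage (pulldown synthesis, DHS synthesis, imputation, ...) hashes the
    master seed together with its stage name so that stages are mutually
    independent but individually reproducible.
    """
    digest = hashlib.blake2b(f"{int(seed)}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of an unambiguous (or N-containing) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
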