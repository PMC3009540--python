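"""Shared error types and deterministic seed derivation."""

from __future__ import annotations

import zlib


class InputError(ValueError):
    """Malformed user input (FASTA, config values)."""


class ConfigError(ValueError):
    """Invalid pipeline or benchmark configuration."""


class ResourceError(RuntimeError):
    """A requested computation exceeds a configured resource cap."""


class PurificationError(RuntimeError):
    """False-positive removal discarded every positive sequence."""


class NoMotifError(RuntimeError):
    """No anchor yielded a motif passing the accuracy threshold."""


def derive_seed(global_seed: int, *tags: object) -> int:
    """Derive a stage seed from the global seed and a tag path.

    Uses CRC32 of the joined tag string so every pipeline stage gets an
    independent, reproducible stream; the result is always < 2**31.
    """
    key = "/".join([str(int(global_seed)), *map(str, tags)])
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
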