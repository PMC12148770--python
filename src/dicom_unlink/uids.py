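"""Generation and validation of DICOM unique identifiers (UI value representation).

Replacement UIDs are minted under the UUID-derived ``2.25.`` root by default,
which needs no registered organisation root and always fits the 64-character
limit. A seeded generator produces a bit-reproducible stream for testing.
"""

from __future__ import annotations

import re
import uuid
from dataclasses import dataclass

__all__ = [
    "DEFAULT_ROOT",
    "UID_MAX_LENGTH",
    "UidGenerator",
    "UidValidity",
    "InvalidRootError",
    "generate_uid",
    "validate_uid",
    "is_valid_uid",
]

DEFAULT_ROOT = "2.25."
UID_MAX_LENGTH = 64

# One dotted-decimal component: "0" or a digit string without a leading zero.
_COMPONENT_RE = re.compile(r"^(0|[1-9][0-9]*)$")

# Namespace for the deterministic (seeded) stream; an arbitrary fixed UUID so
# that seed -> UID sequence is stable across processes and platforms.
_SEED_NAMESPACE = uuid.UUID("6ba7b810-9dad-11d1-80b4-00c04fd430c8")


class InvalidRootError(ValueError):
    """Raised when a configured UID root cannot prefix valid UIDs."""


@dataclass(frozen=True)
class UidValidity:
    """Verdict of :func:`validate_uid`; ``reason`` names the violated rule."""

    valid: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


def validate_uid(candidate: str) -> UidValidity:
    """Check ``candidate`` against the DICOM UI value-representation rules.

    A valid UID is a non-empty dotted-decimal string of at most 64
    characters whose components carry no leading zeros (a bare ``0``
    component is allowed). This is a total function: every input yields a
    verdict, never an exception.
    """
    if not isinstance(candidate, str) or candidate == "":
        return UidValidity(False, "empty")
    if len(candidate) > UID_MAX_LENGTH:
        return UidValidity(False, f"length {len(candidate)} exceeds {UID_MAX_LENGTH}")
    if candidate.startswith(".") or candidate.endswith("."):
        return UidValidity(False, "starts or ends with '.'")
    for component in candidate.split("."):
        if component == "":
            return UidValidity(False, "empty component (consecutive dots)")
        if not _COMPONENT_RE.match(component):
            if component.isdigit():
                return UidValidity(False, f"leading zero in component {component!r}")
            return UidValidity(False, f"non-numeric component {component!r}")
    return UidValidity(True)


def is_valid_uid(candidate: str) -> bool:
    return validate_uid(candidate).valid


def _check_root(root: str) -> str:
    """Validate a UID root; empty string selects :data:`DEFAULT_ROOT`."""
    if root == "":
        return DEFAULT_ROOT
    if not root.endswith("."):
        raise InvalidRootError(f"UID root must end with '.': {root!r}")
    verdict = validate_uid(root[:-1])
    if not verdict.valid:
        raise InvalidRootError(f"invalid UID root {root!r}: {verdict.reason}")
    # Room for at least one suffix digit.
    if len(root) >= UID_MAX_LENGTH:
        raise InvalidRootError(f"UID root {root!r} leaves no room for a suffix")
    return root


def _suffix_from_uuid(u: uuid.UUID, max_digits: int) -> str:
    """Render a UUID as a decimal suffix component of at most ``max_digits``."""
    value = u.int
    if max_digits < 39:  # 2**128 has 39 decimal digits
        value %= 10**max_digits
    return str(value)


class UidGenerator:
    """Mint fresh, valid UIDs under a configurable root.

    Without a seed each call draws a random 128-bit UUID (version 4).  With
    ``seed`` set, successive UIDs are derived from a counter-fed name-based
    UUID (version 5), so the stream is reproducible: the same seed always
    yields the same sequence.
    """

    def __init__(self, root: str = "", seed: int | None = None) -> None:
        self.root = _check_root(root)
        self._seed = seed
        self._counter = 0
        self._issued: set[str] = set()

    def __call__(self) -> str:
        max_digits = UID_MAX_LENGTH - len(self.root)
        while True:
            if self._seed is None:
                u = uuid.uuid4()
            else:
                u = uuid.uuid5(_SEED_NAMESPACE, f"{self._seed}:{self._counter}")
            self._counter += 1
            candidate = self.root + _suffix_from_uuid(u, max_digits)
            # Collisions are astronomically unlikely for uuid4 and require a
            # uuid5 cycle for seeded mode, but the uniqueness contract is
            # absolute within one generator.
            if candidate not in self._issued:
                self._issued.add(candidate)
                return candidate


def generate_uid(root: str = "", entropy_source: int | None = None) -> str:
    """Generate one UID; convenience wrapper over :class:`UidGenerator`.

    For reproducible *sequences* keep a single :class:`UidGenerator`
    instance; this wrapper with a fixed ``entropy_source`` always returns the
    first element of that seed's stream.
    """
    return UidGenerator(root, seed=entropy_source)()
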