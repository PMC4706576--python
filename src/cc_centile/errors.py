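"""Error and warning types shared across the pipeline.

Every raised :class:`CCError` carries a short machine-readable ``code``
(e.g. ``"empty-mask"``, ``"slice-miss"``) so batch drivers can log and
continue without parsing messages.
"""

from __future__ import annotations


class CCError(Exception):
    """Pipeline error with a stable short code."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)


class CCWarning(UserWarning):
    """Non-fatal condition (hole filling, non-convergence, tie-breaks...)."""
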