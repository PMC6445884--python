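"""Shared validation error type and tiny check helpers."""

from __future__ import annotations


class ValidationError(ValueError):
    """Raised when an operation's preconditions are violated.

    The message always names the offending parameter.
    """


def check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)
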