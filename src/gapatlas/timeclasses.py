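"""Developmental staging used throughout the package.

Blastoderm embryos are staged into cleavage cycles C10-C13 plus eight
time classes T1-T8 that subdivide cycle 14A (roughly 7 minutes each).
All atlas cells, envelopes and metrics are keyed by these labels; the
package never computes a stage from images, it is supplied as metadata.
"""

from __future__ import annotations

import pandas as pd

TIME_CLASSES: tuple[str, ...] = (
    "C10", "C11", "C12", "C13", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8",
)

TIME_CLASS_DTYPE = pd.CategoricalDtype(categories=list(TIME_CLASSES), ordered=True)

_INDEX = {c: i for i, c in enumerate(TIME_CLASSES)}


def class_index(tc: str) -> int:
    """Position of a time class in the developmental order (0 = C10)."""
    try:
        return _INDEX[tc]
    except KeyError:
        raise ValueError(f"unknown time class {tc!r}; expected one of {TIME_CLASSES}")


def validate_time_class(tc: str) -> str:
    class_index(tc)
    return tc


def sort_classes(classes) -> list[str]:
    """Sort labels into developmental order, dropping duplicates."""
    seen = {validate_time_class(c) for c in classes}
    return [c for c in TIME_CLASSES if c in seen]
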