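"""Packaged reference values for the two species' wild-type patterns.

These tables transcribe the printed summary values of the quantified
*Megaselia abdita* (``mab``) and *Drosophila melanogaster* (``dmel``)
expression datasets: boundary positions at selected time classes, per-gene
embryo counts, and the RNAi penetrance counts. They serve as comparison
fixtures for the metrics and perturbation modules; the underlying embryo
images are not redistributed here.

Each boundary row carries a ``citation`` string restating its source
values, so a fixture-integrity test can verify that no transcription has
drifted.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = [
    "load_reference",
    "wildtype_dataset_totals",
    "rnai_penetrance_counts",
    "citation_numbers",
]

# species, gene, domain_id, edge, time_class, position, citation
_BOUNDARY_ROWS = [
    # --- M. abdita -------------------------------------------------------
    ("mab", "hb", "anterior", "posterior", "C11", 56.0,
     "mab wild type: anterior hb domain 0-56% A-P at C11"),
    ("mab", "hb", "anterior", "posterior", "T8", 48.0,
     "mab wild type: anterior hb posterior boundary shifts 8%EL by T8 (56-8=48)"),
    ("mab", "hb", "posterior", "anterior", "C13", 90.0,
     "mab wild type: posterior hb domain extends to 90% A-P at C12/C13"),
    ("mab", "hb", "posterior", "anterior", "T2", 84.0,
     "mab wild type: posterior hb anterior border at 84% A-P by T2"),
    ("mab", "hb", "posterior", "anterior", "T8", 72.0,
     "mab wild type: posterior hb at 72-84% A-P at T8"),
    ("mab", "hb", "posterior", "posterior", "T8", 84.0,
     "mab wild type: posterior hb at 72-84% A-P at T8"),
    ("mab", "Kr", "central", "anterior", "C12", 40.0,
     "mab wild type: central Kr domain between 40 and 63% A-P at C12"),
    ("mab", "Kr", "central", "posterior", "C12", 63.0,
     "mab wild type: central Kr domain between 40 and 63% A-P at C12"),
    ("mab", "Kr", "central", "anterior", "T8", 37.0,
     "mab wild type: central Kr at 37-51% A-P at T8"),
    ("mab", "Kr", "central", "posterior", "T8", 51.0,
     "mab wild type: central Kr at 37-51% A-P at T8"),
    ("mab", "gt", "anterior", "anterior", "C12", 14.0,
     "mab wild type: anterior gt stripe at 14-34% A-P at C12"),
    ("mab", "gt", "anterior", "posterior", "C12", 34.0,
     "mab wild type: anterior gt stripe at 14-34% A-P at C12"),
    ("mab", "gt", "anterior", "anterior", "C13", 15.0,
     "mab wild type: anterior gt at 15-35% A-P at C13"),
    ("mab", "gt", "anterior", "posterior", "C13", 35.0,
     "mab wild type: anterior gt at 15-35% A-P at C13"),
    ("mab", "gt", "posterior", "anterior", "C12", 73.0,
     "mab wild type: posterior gt from 73% A-P to the posterior pole at C12"),
    ("mab", "gt", "posterior", "anterior", "C13", 72.0,
     "mab wild type: posterior gt anterior boundary at 72% A-P at C13"),
    ("mab", "gt", "posterior", "anterior", "T8", 62.0,
     "mab wild type: posterior gt anterior boundary shifts to 62% A-P by T8"),
    ("mab", "gt", "posterior", "posterior", "T1", 86.0,
     "mab wild type: posterior gt posterior boundary at 86% A-P at T1"),
    ("mab", "gt", "posterior", "posterior", "T8", 71.0,
     "mab wild type: posterior gt posterior boundary at 71% A-P at T8"),
    ("mab", "kni", "abdominal", "anterior", "C12", 61.0,
     "mab wild type: abdominal kni domain at 61-78% A-P at C12"),
    ("mab", "kni", "abdominal", "posterior", "C12", 78.0,
     "mab wild type: abdominal kni domain at 61-78% A-P at C12"),
    ("mab", "cad", "posterior", "anterior", "T5", 79.0,
     "mab wild type: cad posterior stripe at 79-90% A-P around T5"),
    ("mab", "cad", "posterior", "posterior", "T5", 90.0,
     "mab wild type: cad posterior stripe at 79-90% A-P around T5"),
    # --- D. melanogaster -------------------------------------------------
    ("dmel", "hb", "anterior", "posterior", "C11", 50.0,
     "dmel wild type: anterior hb domain 0-50% A-P"),
    ("dmel", "hb", "posterior", "anterior", "T8", 75.0,
     "dmel wild type: posterior hb at 75-85% A-P at T8"),
    ("dmel", "hb", "posterior", "posterior", "T8", 85.0,
     "dmel wild type: posterior hb at 75-85% A-P at T8"),
    ("dmel", "Kr", "central", "anterior", "T8", 43.0,
     "dmel wild type: central Kr at 43-53% A-P at T8"),
    ("dmel", "Kr", "central", "posterior", "T8", 53.0,
     "dmel wild type: central Kr at 43-53% A-P at T8"),
    ("dmel", "gt", "anterior", "anterior", "C13", 19.0,
     "dmel wild type: anterior gt at 19-40% A-P at C13"),
    ("dmel", "gt", "anterior", "posterior", "C13", 40.0,
     "dmel wild type: anterior gt at 19-40% A-P at C13"),
    ("dmel", "gt", "posterior", "anterior", "C13", 74.0,
     "dmel wild type: posterior gt anterior boundary at 74% A-P at C13"),
    ("dmel", "gt", "posterior", "anterior", "T8", 65.0,
     "dmel wild type: posterior gt anterior boundary at 65% A-P at T8"),
    ("dmel", "gt", "posterior", "posterior", "T1", 82.0,
     "dmel wild type: posterior gt posterior boundary at 82% A-P at T1"),
    ("dmel", "gt", "posterior", "posterior", "T8", 73.0,
     "dmel wild type: posterior gt posterior boundary at 73% A-P at T8"),
]

#: Wild-type trunk-gene dataset: distinct embryos stained per gene (mab).
_WT_TOTALS = {"hb": 91, "Kr": 83, "gt": 87, "kni": 106}

# stained gene, knock-down, n affected, n total, printed percent
_RNAI_COUNTS = [
    ("hb", "gt", 17, 28, 60), ("hb", "Kr", 21, 41, 51),
    ("hb", "kni", 35, 52, 67), ("hb", "tll", 12, 29, 41),
    ("hb", "hkb", 21, 22, 95), ("hb", "tll:hkb", 15, 15, 100),
    ("gt", "hb", 28, 35, 80), ("gt", "Kr", 13, 20, 65),
    ("gt", "kni", 24, 30, 80), ("gt", "tll", 24, 30, 80),
    ("gt", "hkb", 10, 10, 100), ("gt", "tll:hkb", 35, 36, 97),
    ("Kr", "hb", 24, 53, 46), ("Kr", "gt", 7, 17, 41),
    ("Kr", "kni", 26, 40, 65), ("Kr", "tll", 7, 18, 38),
    ("Kr", "hkb", 10, 10, 100), ("Kr", "tll:hkb", 12, 21, 57),
    ("kni", "hb", 9, 14, 64), ("kni", "gt", 11, 25, 44),
    ("kni", "Kr", 3, 21, 14), ("kni", "tll", 6, 44, 14),
    ("kni", "hkb", 4, 10, 40), ("kni", "tll:hkb", 16, 16, 100),
]


def load_reference(species: str) -> pd.DataFrame:
    """Boundary-position fixture for ``species`` in {'mab', 'dmel'}."""
    if species not in {"mab", "dmel"}:
        raise ValueError(f"unknown species {species!r}; expected mab or dmel")
    df = pd.DataFrame(
        [r for r in _BOUNDARY_ROWS if r[0] == species],
        columns=["species", "gene", "domain_id", "edge", "time_class",
                 "position", "citation"])
    return df.reset_index(drop=True)


def wildtype_dataset_totals() -> dict[str, int]:
    """Distinct embryos per trunk gap gene in the mab wild-type dataset."""
    return dict(_WT_TOTALS)


def rnai_penetrance_counts() -> pd.DataFrame:
    """RNAi dataset overview: affected / total counts per stained gene and
    knock-down, with the published integer percentages."""
    return pd.DataFrame(_RNAI_COUNTS, columns=[
        "stained_gene", "knockdown_gene", "n_affected", "n_total",
        "printed_percent"])


def citation_numbers(citation: str) -> list[float]:
    """All numbers occurring in a citation string (for integrity checks)."""
    return [float(m) for m in re.findall(r"\d+(?:\.\d+)?", citation)]
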