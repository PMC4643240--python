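"""Packaged transcriptions of the published per-subject result tables.

Four tables ship with the package (20 subjects each):

* ``table1`` — main-task regression coefficients (expected utility, risk,
  entropy gain) with significance star counts;
* ``table2`` — BIC scores of the choice regression with and without the
  entropy predictor;
* ``table3`` — BIC scores of the four generative model variants
  ({KL-control, expected utility} x {estimated, fixed} precision);
* ``table4`` — winning-model parameters (precision, utilities with outcome
  1 pinned at 0) and their correlation with explicit ratings.

Values are stored to the printed two decimals, with unicode minus signs
normalized to ASCII.  Loading verifies a SHA-256 checksum so silent edits
of the packaged data are caught.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTable", "load_fixture", "column_sum", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table2", "table3", "table4")

_CHECKSUMS = {
    "table1": "ac159815e16cbf5dc334a1c4c7d45a3053b377453eccaa7322d457d518a5ab88",
    "table2": "3403a7ad391359277e7ee47ec1280e696bf19471d2d23d83df59d3e8b31e90f8",
    "table3": "8105473ea9e11810d09c49331efc44c2a7f5ed0e3e30cecd3abf9f40a21335b5",
    "table4": "37c88c4f4a99fca1b3ae74cc806f02fd87081eabad961103a7b669d4e0a80e08",
}


@dataclass(frozen=True)
class FixtureTable:
    name: str
    frame: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.frame)


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged table by name ('table1' .. 'table4')."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("klchoice.data").joinpath(f"{name}.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}.csv checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    with ref.open("r") as fh:
        frame = pd.read_csv(fh)
    return FixtureTable(name=name, frame=frame)


def column_sum(table: FixtureTable, column: str) -> float:
    """Sum of the per-subject entries of a numeric column."""
    col = table.frame[column]
    if not pd.api.types.is_numeric_dtype(col):
        raise TypeError(f"column {column!r} is not numeric")
    return float(col.sum())
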