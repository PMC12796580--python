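"""Deterministic micro-fixtures shared by the test suite.

Each fixture is a JSON data file (inputs, expected outputs, provenance and —
for derived fixtures — a description of the independent oracle that produced
the expected values).  Keeping them as data rather than code lets other
implementations of the same analysis share them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class Fixture:
    """One micro-fixture.

    ``provenance`` says where the expected values come from: ``reported``
    (printed in the experimental literature), ``forced`` (an arithmetic
    identity of the operation's definition) or ``derived`` (computed by the
    independent brute-force oracle described in ``oracle``).
    """

    name: str
    inputs: dict
    expected: dict
    provenance: str  # reported | forced | derived
    oracle: str


def _read(name: str) -> dict:
    ref = resources.files("whiskloop") / "fixture_data" / name
    return json.loads(ref.read_text())


def fixture_names() -> list[str]:
    return list(_read("manifest.json")["fixtures"])


def build_fixture(name: str) -> Fixture:
    """Load a registered fixture by name."""
    if name not in fixture_names():
        raise KeyError(f"unknown fixture {name!r}")
    raw = _read(f"{name}.json")
    return Fixture(
        name=raw["name"],
        inputs=raw["inputs"],
        expected=raw["expected"],
        provenance=raw["provenance"],
        oracle=raw["oracle"],
    )
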