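"""The six-transmitter label space shared by every stage of the pipeline.

All matrices and score vectors in this package are indexed in one canonical
order, fixed here. Input tables may use common abbreviations (ACh, GABA, 5-HT,
...); :func:`normalize_label` maps them onto the canonical names.
"""

from __future__ import annotations

from typing import Iterable, Sequence

#: Canonical label order used for every 6-vector and 6x6 matrix.
TRANSMITTERS: tuple[str, ...] = (
    "gaba",
    "acetylcholine",
    "glutamate",
    "serotonin",
    "octopamine",
    "dopamine",
)

N_TRANSMITTERS = len(TRANSMITTERS)

#: Sentinel for neurons whose majority vote is ambiguous. Not an element of
#: the label space: entropy and Bayes-factor analyses exclude it.
UNCERTAIN = "uncertain"

#: Case-insensitive aliases accepted on input.
ALIASES: dict[str, str] = {
    "gaba": "gaba",
    "ach": "acetylcholine",
    "acetylcholine": "acetylcholine",
    "ach.": "acetylcholine",
    "choline": "acetylcholine",
    "glut": "glutamate",
    "glu": "glutamate",
    "glutamate": "glutamate",
    "ser": "serotonin",
    "5-ht": "serotonin",
    "5ht": "serotonin",
    "serotonin": "serotonin",
    "oct": "octopamine",
    "octopamine": "octopamine",
    "da": "dopamine",
    "dop": "dopamine",
    "dopamine": "dopamine",
    "uncertain": UNCERTAIN,
}

LABEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(TRANSMITTERS)}

#: Score columns in the canonical order, e.g. ``score_gaba``.
SCORE_COLUMNS: tuple[str, ...] = tuple(f"score_{t}" for t in TRANSMITTERS)

#: Compartment vocabulary for presynapse locations.
COMPARTMENTS: frozenset[str] = frozenset(
    {"axon", "dendrite", "soma", "primary_dendrite", "cell_body_fiber", "unknown"}
)


class VocabularyError(ValueError):
    """An input label is not one of the six transmitters (or a known alias)."""


def normalize_label(label: str) -> str:
    """Map ``label`` (case-insensitive, alias-tolerant) to its canonical name.

    Raises
    ------
    VocabularyError
        If the label is not a transmitter name, known alias, or "uncertain".
    """
    key = str(label).strip().lower()
    try:
        return ALIASES[key]
    except KeyError:
        raise VocabularyError(
            f"unknown transmitter label {label!r}; expected one of "
            f"{sorted(set(ALIASES))}"
        ) from None


def normalize_labels(labels: Iterable[str]) -> list[str]:
    """Vectorized :func:`normalize_label`; collects all offenders into one error."""
    out: list[str] = []
    bad: list[str] = []
    for lab in labels:
        key = str(lab).strip().lower()
        hit = ALIASES.get(key)
        if hit is None:
            bad.append(str(lab))
        else:
            out.append(hit)
    if bad:
        raise VocabularyError(
            f"unknown transmitter labels: {sorted(set(bad))}"
        )
    return out


def label_indices(labels: Sequence[str]) -> list[int]:
    """Canonical indices of already-normalized transmitter labels."""
    return [LABEL_INDEX[lab] for lab in labels]
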