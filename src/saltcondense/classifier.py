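"""Amino-acid-composition classifier of salt-dependence classes.

Homotypic IDP phase separation responds to salt in four qualitatively
distinct ways — screening, reentrant, high net charge, low net charge —
and the class is largely predictable from three composition features,
measured as percentages of sequence length:

    chg_pct = 100 * (n_pos + n_neg) / length     (threshold 20%)
    net_pct = 100 * |net_charge| / length        (threshold 6%)
    aro_pct = 100 * n_aromatic / length          (threshold 8%)

Thresholds are inclusive (a protein at exactly 20.0% charged content counts
as high).  Aromatic residues are W, Y and F; positive residues R and K (plus
H under the low-pH flag); negative D and E.  A phospho-Tyr contributes two
negative charge units and is no longer counted as aromatic.

The rule table:

    chg high, net low, aro low   -> screening
    chg high, net low, aro high  -> reentrant
    net high, aro high           -> high_net_charge
    chg low, net low, aro high   -> low_net_charge
    anything else                -> indeterminate

A packaged transcription of the 27-protein validation table ships with the
module, including the published high/low markers for every feature.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources

CLASSES = ("screening", "reentrant", "high_net_charge", "low_net_charge")

DEFAULT_THRESHOLDS = (20.0, 6.0, 8.0)

_AROMATIC_LETTERS = set("WYF")
_POSITIVE_LETTERS = set("RK")
_NEGATIVE_LETTERS = set("DE")
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_TABLE1_SHA256 = "862ba12d062f8368062529e76e93f2a1910a66f8e6d51685f58f7f5498e3c877"


@dataclass
class CompositionRecord:
    """Sequence-composition counts for one protein.

    ``n_pos``/``n_neg`` are charge-unit counts (a phospho-Tyr contributes 2
    negative units), so ``net_charge = n_pos - n_neg`` holds identically.
    """

    name: str
    length: int
    n_pos: int
    n_neg: int
    net_charge: int
    n_aromatic: int
    observed_class: str | None = None
    notes: str = ""

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.observed_class is not None and self.observed_class not in CLASSES:
            raise ValueError(f"unknown class {self.observed_class!r}")


@dataclass
class ClassFlags:
    chg_pct: float
    net_pct: float
    aro_pct: float
    chg_high: bool
    net_high: bool
    aro_high: bool


@dataclass
class ClassPrediction:
    predicted: str                     # a class name or "indeterminate"
    flags: ClassFlags
    rule: str


def composition_from_sequence(sequence: str, name: str = "",
                              protonate_his: bool = False,
                              phospho_tyr_positions=()) -> CompositionRecord:
    """Composition counts from a one-letter sequence.

    ``phospho_tyr_positions`` are 0-based indices of phosphorylated Tyr;
    each adds two negative charge units and removes one aromatic.
    ``protonate_his`` counts His as +1 (low-pH behaviour).
    """
    seq = sequence.upper()
    for i, c in enumerate(seq):
        if c not in _ALPHABET:
            raise ValueError(f"invalid residue letter {c!r} at position {i}")
    phospho = set(int(p) for p in phospho_tyr_positions)
    for p in phospho:
        if not 0 <= p < len(seq) or seq[p] != "Y":
            raise ValueError(f"phospho position {p} is not a Tyr")
    n_pos = sum(1 for c in seq if c in _POSITIVE_LETTERS)
    if protonate_his:
        n_pos += seq.count("H")
    n_neg = sum(1 for c in seq if c in _NEGATIVE_LETTERS) + 2 * len(phospho)
    n_aro = sum(1 for c in seq if c in _AROMATIC_LETTERS) - len(phospho)
    return CompositionRecord(name=name, length=len(seq), n_pos=n_pos,
                             n_neg=n_neg, net_charge=n_pos - n_neg,
                             n_aromatic=n_aro)


def class_flags(record: CompositionRecord,
                thresholds=DEFAULT_THRESHOLDS,
                inclusive: bool = True) -> ClassFlags:
    """Feature percentages and their high/low flags (inclusive thresholds)."""
    chg_t, net_t, aro_t = thresholds
    chg = 100.0 * (record.n_pos + record.n_neg) / record.length
    net = 100.0 * abs(record.net_charge) / record.length
    aro = 100.0 * record.n_aromatic / record.length
    cmp = (lambda v, t: v >= t) if inclusive else (lambda v, t: v > t)
    return ClassFlags(chg, net, aro,
                      cmp(chg, chg_t), cmp(net, net_t), cmp(aro, aro_t))


def predict_class(flags: ClassFlags) -> ClassPrediction:
    """Deterministic class prediction from the three feature flags."""
    c, n, a = flags.chg_high, flags.net_high, flags.aro_high
    if n and a:
        return ClassPrediction("high_net_charge", flags, "net_high & aro_high")
    if c and not n and not a:
        return ClassPrediction("screening", flags,
                               "chg_high & ~net_high & ~aro_high")
    if c and not n and a:
        return ClassPrediction("reentrant", flags,
                               "chg_high & ~net_high & aro_high")
    if not c and not n and a:
        return ClassPrediction("low_net_charge", flags,
                               "~chg_high & ~net_high & aro_high")
    return ClassPrediction("indeterminate", flags, "no rule fired")


def classify_sequence(sequence: str, name: str = "", **kw) -> ClassPrediction:
    """Convenience: sequence -> composition -> flags -> prediction."""
    return predict_class(class_flags(composition_from_sequence(
        sequence, name=name, **kw)))


# ---------------------------------------------------------------------------
# packaged validation table
# ---------------------------------------------------------------------------


@dataclass
class Table1Row:
    record: CompositionRecord
    published_flags: tuple      # (chg_high, net_high, aro_high) markers


def table1_fixture() -> list[Table1Row]:
    """The packaged 27-protein validation table (checksum-verified).

    Charge counts are stored as the published charge-unit counts, so the
    phospho-Tyr variant carries its table values directly.
    """
    data = (resources.files("saltcondense") / "data" / "table1.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError("table1.tsv checksum mismatch; fixture corrupted")
    rows = []
    reader = csv.DictReader(data.decode().splitlines(), delimiter="\t")
    for rec in reader:
        record = CompositionRecord(
            name=rec["name"], length=int(rec["length"]),
            n_pos=int(rec["n_pos"]), n_neg=int(rec["n_neg"]),
            net_charge=int(rec["net_charge"]),
            n_aromatic=int(rec["n_aromatic"]),
            observed_class=rec["observed_class"],
            notes=rec.get("notes") or "")
        flags = (bool(int(rec["bold_chg"])), bool(int(rec["bold_net"])),
                 bool(int(rec["bold_aro"])))
        rows.append(Table1Row(record, flags))
    if len(rows) != 27:
        raise ValueError(f"expected 27 table rows, found {len(rows)}")
    return rows


@dataclass
class Table1Validation:
    """The six published validation statistics plus flag concordance."""

    aro_high_in_aromatic_classes: tuple    # (count, denom) over 17
    aro_high_in_screening: tuple           # over 10
    net_high_in_high_net: tuple            # over 10
    net_high_in_low_net_classes: tuple     # over 17
    chg_high_in_chg_classes: tuple         # over 15
    chg_high_in_other: tuple               # over 12
    flag_matches: int = 0                  # of 81 published markers
    flag_total: int = 81
    mismatches: list = field(default_factory=list)

    @staticmethod
    def _pct(pair):
        return 100.0 * pair[0] / pair[1]

    def percentages(self) -> dict[str, float]:
        return {
            "aro_high_in_aromatic_classes": self._pct(self.aro_high_in_aromatic_classes),
            "aro_high_in_screening": self._pct(self.aro_high_in_screening),
            "net_high_in_high_net": self._pct(self.net_high_in_high_net),
            "net_high_in_low_net_classes": self._pct(self.net_high_in_low_net_classes),
            "chg_high_in_chg_classes": self._pct(self.chg_high_in_chg_classes),
            "chg_high_in_other": self._pct(self.chg_high_in_other),
        }


def validate_table1(rows: list[Table1Row] | None = None,
                    thresholds=DEFAULT_THRESHOLDS) -> Table1Validation:
    """Recompute the validation statistics from the composition table.

    Group fractions test each determinant against the classes that require
    it: aromatic content in the three aromatic-requiring classes vs
    screening; net charge in the high-net-charge class vs the rest; charged
    content in screening+reentrant vs the rest.  Also compares the computed
    flags against the 81 published high/low markers.
    """
    rows = table1_fixture() if rows is None else rows
    if not rows:
        raise ValueError("no records to validate")
    for row in rows:
        if row.record.observed_class is None:
            raise ValueError(f"record {row.record.name!r} lacks a class label")
    flags = {row.record.name: class_flags(row.record, thresholds) for row in rows}

    def group(classes):
        return [r for r in rows if r.record.observed_class in classes]

    def count(rs, attr):
        return sum(1 for r in rs if getattr(flags[r.record.name], attr))

    aromatic_req = group({"reentrant", "high_net_charge", "low_net_charge"})
    screening = group({"screening"})
    high_net = group({"high_net_charge"})
    low_net_req = group({"screening", "reentrant", "low_net_charge"})
    chg_req = group({"screening", "reentrant"})
    chg_not_req = group({"high_net_charge", "low_net_charge"})

    matches, mismatches = 0, []
    for row in rows:
        f = flags[row.record.name]
        computed = (f.chg_high, f.net_high, f.aro_high)
        for feat, got, pub in zip(("chg", "net", "aro"), computed,
                                  row.published_flags):
            if got == pub:
                matches += 1
            else:
                mismatches.append((row.record.name, feat, pub, got))

    return Table1Validation(
        aro_high_in_aromatic_classes=(count(aromatic_req, "aro_high"),
                                      len(aromatic_req)),
        aro_high_in_screening=(count(screening, "aro_high"), len(screening)),
        net_high_in_high_net=(count(high_net, "net_high"), len(high_net)),
        net_high_in_low_net_classes=(count(low_net_req, "net_high"),
                                     len(low_net_req)),
        chg_high_in_chg_classes=(count(chg_req, "chg_high"), len(chg_req)),
        chg_high_in_other=(count(chg_not_req, "chg_high"), len(chg_not_req)),
        flag_matches=matches, flag_total=3 * len(rows),
        mismatches=mismatches)
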