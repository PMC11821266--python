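"""Bias-probing train/test split construction.

Three holdout rules, each designed to defeat a different memorization
shortcut:

* zero-ligand-bias: clusters of identical ligands (matched by InChI-Key)
  bound to different proteins, kept only if the cluster's mean pK lies in
  a central band and its variance is large — so predicting per-ligand
  values cannot score well and ligand identity carries no usable signal;
* peptide holdout: complexes whose ligand code contains "MER"
  (1MER/2MER/... peptide codes) are held out, testing generalization from
  small molecules to peptides;
* time split: complexes deposited at or after a cutoff year form the
  test set.

Every produced split is validated generically: train/test disjoint, the
rule predicate true on every test member, and the accounting
train + test + excluded = dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LigandCluster",
    "BenchmarkSplit",
    "cluster_by_inchikey",
    "zero_ligand_bias_filter",
    "peptide_holdout",
    "time_split",
    "validate_split",
    "write_split",
]


@dataclass
class LigandCluster:
    """All complexes sharing one InChI-Key (>= 2 occurrences)."""

    inchikey: str
    member_ids: list[str]
    pk_values: list[float]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a ligand cluster needs at least 2 members")
        if len(self.member_ids) != len(self.pk_values):
            raise ValueError("member/pk length mismatch")

    @property
    def mean_pk(self) -> float:
        return float(np.mean(self.pk_values))

    @property
    def var_pk(self) -> float:
        # sample variance (n-1 denominator); recorded in split rule metadata
        return float(np.var(self.pk_values, ddof=1))

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class BenchmarkSplit:
    """Disjoint train/test ID sets plus the rule that produced them."""

    name: str
    train_ids: set[str]
    test_ids: set[str]
    excluded_ids: set[str] = field(default_factory=set)
    rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.train_ids & self.test_ids
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(i, "train") for i in sorted(self.train_ids)]
            + [(i, "test") for i in sorted(self.test_ids)]
            + [(i, "excluded") for i in sorted(self.excluded_ids)]
        )
        return pd.DataFrame(rows, columns=["complex_id", "role"])


def cluster_by_inchikey(records: Sequence) -> tuple[list[LigandCluster], list[str]]:
    """Group records by ligand InChI-Key.

    Only keys occurring at least twice yield clusters; IDs of
    singleton-key records are returned separately.
    """
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(rec.ligand.inchikey, []).append(rec)
    clusters = []
    singletons = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) >= 2:
            clusters.append(
                LigandCluster(
                    inchikey=key,
                    member_ids=[m.complex_id for m in members],
                    pk_values=[m.label.pk for m in members],
                )
            )
        else:
            singletons.append(members[0].complex_id)
    return clusters, singletons


def zero_ligand_bias_filter(
    records: Sequence,
    clusters: list[LigandCluster] | None = None,
    mean_range: tuple[float, float] = (6.0, 7.0),
    var_min: float = 1.0,
    exclude_test_ligands_from_train: bool = True,
) -> BenchmarkSplit:
    """Build the zero-ligand-bias split.

    Test set: members of every duplicate-ligand cluster whose mean pK is
    within ``mean_range`` (endpoints inclusive) and whose sample variance
    exceeds ``var_min`` (strict).  With the default leak guard, any
    training record sharing an InChI-Key with a test record is excluded
    from train as well, so no test ligand is ever seen in training.
    """
    if clusters is None:
        clusters, _ = cluster_by_inchikey(records)
    lo, hi = mean_range
    test_keys = set()
    test_ids: set[str] = set()
    for cl in clusters:
        if lo <= cl.mean_pk <= hi and cl.var_pk > var_min:
            test_keys.add(cl.inchikey)
            test_ids.update(cl.member_ids)
    if not test_ids:
        warnings.warn("zero-ligand-bias filter produced an empty test set", stacklevel=2)
    train_ids: set[str] = set()
    excluded: set[str] = set()
    for rec in records:
        if rec.complex_id in test_ids:
            continue
        if exclude_test_ligands_from_train and rec.ligand.inchikey in test_keys:
            excluded.add(rec.complex_id)
        else:
            train_ids.add(rec.complex_id)
    return BenchmarkSplit(
        name="zero_ligand_bias",
        train_ids=train_ids,
        test_ids=test_ids,
        excluded_ids=excluded,
        rule={
            "kind": "zero_ligand_bias",
            "mean_range": [lo, hi],
            "mean_endpoints": "inclusive",
            "var_min": var_min,
            "variance": "sample (ddof=1), strictly greater",
            "train_ligand_leak_guard": exclude_test_ligands_from_train,
        },
    )


def peptide_holdout(records: Sequence, code_substring: str = "MER") -> BenchmarkSplit:
    """Hold out complexes whose ligand code contains a substring.

    Matching is case-insensitive (component codes are conventionally
    upper case but files vary).
    """
    needle = code_substring.upper()
    test_ids = {
        r.complex_id for r in records if needle in (r.ligand.code or "").upper()
    }
    if not test_ids:
        warnings.warn(f"no ligand code contains {code_substring!r}", stacklevel=2)
    train_ids = {r.complex_id for r in records} - test_ids
    return BenchmarkSplit(
        name="peptide_holdout",
        train_ids=train_ids,
        test_ids=test_ids,
        rule={"kind": "peptide_holdout", "code_substring": needle, "case": "insensitive"},
    )


def time_split(records: Sequence, cutoff_year: int = 2019) -> BenchmarkSplit:
    """Deposition-time split: test = year >= cutoff (inclusive).

    Records with no year are placed in neither set and reported as
    excluded.
    """
    test_ids, train_ids, excluded = set(), set(), set()
    for r in records:
        if r.year is None:
            excluded.add(r.complex_id)
        elif r.year >= cutoff_year:
            test_ids.add(r.complex_id)
        else:
            train_ids.add(r.complex_id)
    if not test_ids:
        warnings.warn(f"no record deposited in {cutoff_year} or later", stacklevel=2)
    return BenchmarkSplit(
        name="time_split",
        train_ids=train_ids,
        test_ids=test_ids,
        excluded_ids=excluded,
        rule={"kind": "time_split", "cutoff_year": cutoff_year, "cutoff": "inclusive"},
    )


def validate_split(split: BenchmarkSplit, records: Sequence) -> None:
    """Generic split validator; raises AssertionError on violation.

    Checks disjointness, coverage accounting (train + test + excluded =
    dataset) and the truth of the constructing rule's predicate on every
    test member.
    """
    all_ids = {r.complex_id for r in records}
    by_id = {r.complex_id: r for r in records}
    assert not (split.train_ids & split.test_ids), "train/test overlap"
    assert not (split.train_ids & split.excluded_ids), "train/excluded overlap"
    assert not (split.test_ids & split.excluded_ids), "test/excluded overlap"
    union = split.train_ids | split.test_ids | split.excluded_ids
    assert union == all_ids, "split does not account for every dataset ID"

    kind = split.rule.get("kind")
    if kind == "time_split":
        cutoff = split.rule["cutoff_year"]
        for cid in split.test_ids:
            assert by_id[cid].year is not None and by_id[cid].year >= cutoff
        for cid in split.train_ids:
            assert by_id[cid].year is not None and by_id[cid].year < cutoff
    elif kind == "peptide_holdout":
        needle = split.rule["code_substring"]
        for cid in split.test_ids:
            assert needle in (by_id[cid].ligand.code or "").upper()
        for cid in split.train_ids:
            assert needle not in (by_id[cid].ligand.code or "").upper()
    elif kind == "zero_ligand_bias":
        lo, hi = split.rule["mean_range"]
        var_min = split.rule["var_min"]
        test_keys = {by_id[cid].ligand.inchikey for cid in split.test_ids}
        clusters, _ = cluster_by_inchikey(records)
        by_key = {c.inchikey: c for c in clusters}
        for key in test_keys:
            cl = by_key[key]
            assert lo <= cl.mean_pk <= hi and cl.var_pk > var_min
        if split.rule.get("train_ligand_leak_guard"):
            train_keys = {by_id[cid].ligand.inchikey for cid in split.train_ids}
            assert not (train_keys & test_keys), "test ligand leaked into train"


def write_split(split: BenchmarkSplit, csv_path: str | Path, rule_path: str | Path | None = None) -> None:
    """Write a split as a two-column CSV plus a JSON rule descriptor."""
    import json

    split.to_frame().to_csv(csv_path, index=False)
    if rule_path is not None:
        Path(rule_path).write_text(json.dumps(split.rule, indent=1, sort_keys=True))
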