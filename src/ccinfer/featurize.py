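"""Descriptor vocabularies and feature-matrix assembly.

A vocabulary is the deterministic, ordered collection of enumerative
descriptors (fringe-, adjacency-, edge-, leaf-adjacency- and
cycle-configurations) that occur in a data set; it fixes the coordinates
of the feature vector.  The 2L+CC feature vector of a molecule is the
2L vector followed by the CC vector, f(C) = (f_2L(C), f_CC(C)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .chemgraph import ChemicalGraph, validate
from .cycleconf import CCParams, cc_key, cycle_config_of, enumerate_chordless_cycles
from .elements import ElementTable, default_element_table
from .twolayer import count_configs, decompose, default_static_names, static_descriptors

log = logging.getLogger(__name__)

MODES = ("2L", "2L+CC")


def _ac_name(ac: tuple) -> str:
    a, b, m = ac
    return f"{a}-{b}-{m}"


def _ec_name(ec: tuple) -> str:
    (a, d), (b, d2), m = ec
    return f"{a}{d}-{b}{d2}-{m}"


def cc_name(xi: Sequence[int]) -> str:
    return ".".join(str(r) for r in xi)


@dataclass
class DescriptorVocabulary:
    """Ordered, duplicate-free descriptor collections extracted from a data set."""

    fringe_configs: list[str] = field(default_factory=list)
    acs: list[tuple] = field(default_factory=list)
    ecs: list[tuple] = field(default_factory=list)
    leaf_acs: list[tuple] = field(default_factory=list)
    ccs: list[tuple] = field(default_factory=list)
    static_names: list[str] = field(default_factory=list)

    def columns_2l(self) -> list[str]:
        return (list(self.static_names)
                + [f"fc:{c}" for c in self.fringe_configs]
                + [f"ac:{_ac_name(a)}" for a in self.acs]
                + [f"ec:{_ec_name(e)}" for e in self.ecs]
                + [f"lac:{_ac_name(a)}" for a in self.leaf_acs])

    def columns_cc(self) -> list[str]:
        return [f"cc:{cc_name(x)}" for x in self.ccs]

    def columns(self, mode: str = "2L+CC") -> list[str]:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        cols = self.columns_2l()
        if mode == "2L+CC":
            cols += self.columns_cc()
        return cols

    @property
    def k_2l(self) -> int:
        return len(self.columns_2l())

    @property
    def k_cc(self) -> int:
        return len(self.ccs)

    def to_json(self) -> str:
        return json.dumps({
            "fringe_configs": self.fringe_configs,
            "acs": [[a, b, m] for a, b, m in self.acs],
            "ecs": [[list(p), list(q), m] for p, q, m in self.ecs],
            "leaf_acs": [[a, b, m] for a, b, m in self.leaf_acs],
            "ccs": [list(x) for x in self.ccs],
            "static_names": self.static_names,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DescriptorVocabulary":
        raw = json.loads(text)
        return cls(
            fringe_configs=list(raw["fringe_configs"]),
            acs=[(a, b, int(m)) for a, b, m in raw["acs"]],
            ecs=[((p[0], int(p[1])), (q[0], int(q[1])), int(m)) for p, q, m in raw["ecs"]],
            leaf_acs=[(a, b, int(m)) for a, b, m in raw["leaf_acs"]],
            ccs=[tuple(int(r) for r in x) for x in raw["ccs"]],
            static_names=list(raw["static_names"]),
        )


def _ac_sort_key(table: ElementTable):
    return lambda ac: (table.rank(ac[0]), table.rank(ac[1]), ac[2])


def _ec_sort_key(table: ElementTable):
    return lambda ec: (table.rank(ec[0][0]), ec[0][1], table.rank(ec[1][0]), ec[1][1], ec[2])


def build_vocabulary(dataset: Iterable[ChemicalGraph],
                     params: CCParams = CCParams(),
                     rho: int = 2,
                     table: ElementTable | None = None,
                     static_names: list[str] | None = None) -> DescriptorVocabulary:
    """Collect every descriptor occurring in the data set, in a fixed order.

    All molecules must pass :func:`ccinfer.chemgraph.validate`.  Orders:
    fringe codes lexicographic, AC/EC by (element rank, degree,
    multiplicity), CCs by (length, rank sequence); all shuffle-invariant.
    """
    table = table or default_element_table()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("cannot build a vocabulary from an empty data set")
    fringe: set[str] = set()
    acs: set[tuple] = set()
    ecs: set[tuple] = set()
    lacs: set[tuple] = set()
    ccs: set[tuple] = set()
    elements: set[str] = set()
    for mol in dataset:
        problems = validate(mol, table)
        if problems:
            raise ValueError(f"invalid molecule in data set: {problems}")
        decomp = decompose(mol, rho, table)
        counts = count_configs(mol, decomp, table)
        fringe.update(counts["fringe"])
        acs.update(counts["ac"])
        ecs.update(counts["ec"])
        lacs.update(counts["leaf_ac"])
        for cyc in enumerate_chordless_cycles(decomp.suppressed, params):
            ccs.add(cycle_config_of(cyc, decomp, table))
        elements.update(decomp.suppressed.element(v) for v in decomp.suppressed.atoms())
    if static_names is None:
        static_names = default_static_names(sorted(elements, key=table.rank))
    return DescriptorVocabulary(
        fringe_configs=sorted(fringe),
        acs=sorted(acs, key=_ac_sort_key(table)),
        ecs=sorted(ecs, key=_ec_sort_key(table)),
        leaf_acs=sorted(lacs, key=_ac_sort_key(table)),
        ccs=sorted(ccs, key=cc_key),
        static_names=list(static_names),
    )


def feature_vector(mol: ChemicalGraph, vocab: DescriptorVocabulary,
                   mode: str = "2L+CC",
                   params: CCParams = CCParams(),
                   rho: int = 2,
                   table: ElementTable | None = None,
                   warn_oov: bool = True) -> list[float]:
    """f(C) over the vocabulary coordinates; out-of-vocabulary patterns score 0."""
    table = table or default_element_table()
    decomp = decompose(mol, rho, table)
    counts = count_configs(mol, decomp, table)
    vec: list[float] = list(static_descriptors(mol, decomp, vocab.static_names, table))
    oov: list[str] = []

    def emit(counter, keys, namer):
        known = set(keys)
        for k in keys:
            vec.append(float(counter.get(k, 0)))
        for k in counter:
            if k not in known:
                oov.append(namer(k))

    emit(counts["fringe"], vocab.fringe_configs, lambda c: f"fc:{c}")
    emit(counts["ac"], vocab.acs, lambda a: f"ac:{_ac_name(a)}")
    emit(counts["ec"], vocab.ecs, lambda e: f"ec:{_ec_name(e)}")
    emit(counts["leaf_ac"], vocab.leaf_acs, lambda a: f"lac:{_ac_name(a)}")
    if mode == "2L+CC":
        from collections import Counter

        cc_counts: Counter = Counter()
        for cyc in enumerate_chordless_cycles(decomp.suppressed, params):
            cc_counts[cycle_config_of(cyc, decomp, table)] += 1
        emit(cc_counts, [tuple(x) for x in vocab.ccs], lambda x: f"cc:{cc_name(x)}")
    elif mode != "2L":
        raise ValueError(f"mode must be one of {MODES}")
    if oov and warn_oov:
        log.warning("molecule contains %d descriptor(s) outside the vocabulary: %s",
                    len(oov), ", ".join(sorted(oov)))
    return vec


def featurize_dataset(dataset: Sequence[ChemicalGraph],
                      vocab: DescriptorVocabulary,
                      mode: str = "2L+CC",
                      ids: Sequence | None = None,
                      params: CCParams = CCParams(),
                      rho: int = 2,
                      table: ElementTable | None = None) -> pd.DataFrame:
    """Feature matrix of a data set: one row per molecule, one column per descriptor.

    Molecules failing validation are skipped with a logged reason (the
    skipped ids are recorded in ``df.attrs["skipped"]``); molecules with
    out-of-vocabulary patterns get zeros there, with a logged warning.
    """
    table = table or default_element_table()
    if ids is None:
        ids = list(range(len(dataset)))
    rows = {}
    skipped = []
    for mol_id, mol in zip(ids, dataset):
        problems = validate(mol, table)
        if problems:
            log.warning("skipping molecule %r: %s", mol_id, "; ".join(problems))
            skipped.append((mol_id, "; ".join(problems)))
            continue
        rows[mol_id] = feature_vector(mol, vocab, mode, params, rho, table)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=vocab.columns(mode))
    df.attrs["mode"] = mode
    df.attrs["skipped"] = skipped
    return df


def filter_feasible(dataset: Sequence[ChemicalGraph],
                    element_set: Iterable[str],
                    table: ElementTable | None = None,
                    min_carbons: int = 4,
                    ids: Sequence | None = None):
    """Split a data set into 2L-feasible molecules and excluded ones.

    Kept molecules are connected, contain at least ``min_carbons`` carbon
    atoms, use only elements of ``element_set`` (hydrogen is always
    allowed) and have a non-empty interior.  Returns
    ``(kept_ids, excluded)`` where ``excluded`` is a list of
    ``(id, reason)`` pairs.
    """
    table = table or default_element_table()
    allowed = set(element_set) | {"H"}
    if ids is None:
        ids = list(range(len(dataset)))
    kept, excluded = [], []
    for mol_id, mol in zip(ids, dataset):
        bad_elem = sorted({mol.element(v) for v in mol.atoms()} - allowed)
        if bad_elem:
            excluded.append((mol_id, f"element: {', '.join(bad_elem)}"))
            continue
        problems = validate(mol, table, min_carbons=min_carbons)
        carbon_problem = [p for p in problems if "carbon atoms" in p]
        if carbon_problem:
            excluded.append((mol_id, "carbon count"))
            continue
        if problems:
            excluded.append((mol_id, "; ".join(problems)))
            continue
        kept.append(mol_id)
    return kept, excluded
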