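"""Reaction / EC-label parsing, dataset loading, CV folds and fixture corpora.

Reactions are daylight reaction SMILES ``reactants>agents>products``; EC
labels are the hierarchical Enzyme Commission strings ``x.y.z.sn``.  Class 7
(translocases) is filtered on load: translocation across a membrane encodes
no chemical transformation, so a reaction-based classifier has nothing to
learn from it.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError, FormatError, InputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ECLabel",
    "ReactionRecord",
    "FixtureTemplate",
    "FixtureConfig",
    "parse_ec",
    "parse_reaction_smiles",
    "load_reaction_dataset",
    "make_cv_folds",
    "generate_fixture_corpus",
    "default_fixture_config",
    "records_to_csv",
    "records_to_dataframe",
]


# --------------------------------------------------------------------------
# EC labels
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ECLabel:
    """Hierarchical EC number x.y.z.sn with left-to-right optional levels."""

    x: int
    y: Optional[int] = None
    z: Optional[int] = None
    sn: Optional[int] = None

    def __post_init__(self) -> None:
        levels = (self.y, self.z, self.sn)
        seen_none = False
        for lv in levels:
            if lv is None:
                seen_none = True
            elif seen_none:
                raise ParseError(f"EC levels must be filled left-to-right: {self}")
        if not 1 <= self.x <= 7:
            raise ParseError(f"EC class must be 1..7, got {self.x}")

    @property
    def level(self) -> int:
        return 4 - (self.y, self.z, self.sn).count(None)

    def render(self, level: Optional[int] = None) -> str:
        """Dotted string at the given level (default: all populated levels)."""
        parts = [self.x, self.y, self.z, self.sn]
        if level is None:
            level = self.level
        if not 1 <= level <= self.level:
            raise InputError(f"cannot render {self} at level {level}")
        return ".".join(str(p) for p in parts[:level])

    def truncate(self, level: int) -> str:
        return self.render(level)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_ec(s: str) -> ECLabel:
    """Parse ``"3.4.13"`` -> ECLabel(3, 4, 13).

    Each dot-separated field must be a non-negative integer; 1-4 fields.
    """
    fields = s.strip().split(".")
    if not 1 <= len(fields) <= 4:
        raise ParseError(f"EC string must have 1-4 fields: {s!r}")
    values = []
    for f in fields:
        if not f.isdigit():
            raise ParseError(f"non-numeric EC field {f!r} in {s!r}")
        values.append(int(f))
    values += [None] * (4 - len(values))
    return ECLabel(*values)


# --------------------------------------------------------------------------
# Reaction SMILES
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionRecord:
    """One reaction SMILES with its EC annotation and provenance tag."""

    reaction_smiles: str
    ec: ECLabel
    source: str = "fixture"


def _parse_molecules(block: str, what: str) -> list[Chem.Mol]:
    mols = []
    if not block:
        return mols
    for token in block.split("."):
        mol = Chem.MolFromSmiles(token)
        if mol is None:
            raise ParseError(f"unparsable {what} SMILES token {token!r}")
        mols.append(mol)
    return mols


def parse_reaction_smiles(s: str) -> tuple[list[Chem.Mol], list[Chem.Mol], list[Chem.Mol]]:
    """Split ``reactants>agents>products`` and parse every molecule.

    Returns (reactants, agents, products) in input order.  The agents part
    may be empty; at least one reactant and one product are required.
    """
    parts = s.split(">")
    if len(parts) != 3:
        raise FormatError(
            f"reaction SMILES must have 3 '>'-separated parts, got {len(parts)}: {s!r}"
        )
    reactants = _parse_molecules(parts[0], "reactant")
    agents = _parse_molecules(parts[1], "agent")
    products = _parse_molecules(parts[2], "product")
    if not reactants or not products:
        raise FormatError(f"reaction needs >=1 reactant and >=1 product: {s!r}")
    return reactants, agents, products


# --------------------------------------------------------------------------
# Dataset loading
# --------------------------------------------------------------------------

_DIALECTS = {
    "rhea_csv": {"smiles": "rxn_smiles", "ec": "ec"},
    "ecreact_csv": {"smiles": "rxn_smiles", "ec": "ec"},
}

# ECREACT embeds the EC number inside the reactant block: "CC.O|1.1.1.1>>CCO"
_EMBEDDED_EC = re.compile(r"\|(\d+(?:\.\d+){0,3})(?=>)")


@dataclass
class LoadReport:
    """Accounting of a dataset load: kept rows plus categorised rejects."""

    n_rows: int = 0
    n_kept: int = 0
    n_class7: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)


def load_reaction_dataset(
    path,
    dialect: str = "rhea_csv",
    *,
    report: Optional[LoadReport] = None,
) -> list[ReactionRecord]:
    """Load a reaction CSV in the ``rhea_csv`` or ``ecreact_csv`` dialect.

    Both dialects carry columns ``rxn_smiles`` and ``ec``; ecreact_csv adds a
    ``source`` column and may embed an ``|x.y.z.sn`` EC token inside the
    SMILES, which is stripped before storage.  EC class 7 rows are dropped.
    Rows with invalid SMILES or EC strings are skipped with a warning and
    counted in the report.  SMILES (including stereochemistry) are stored
    verbatim apart from the embedded-token strip.
    """
    if dialect not in _DIALECTS:
        raise InputError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
    cols = _DIALECTS[dialect]
    df = pd.read_csv(path)
    for col in (cols["smiles"], cols["ec"]):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} (dialect {dialect})")
    if report is None:
        report = LoadReport()
    report.n_rows = len(df)

    records: list[ReactionRecord] = []
    default_source = "ecreact" if dialect == "ecreact_csv" else "rhea"
    for i, row in df.iterrows():
        smiles = str(row[cols["smiles"]])
        ec_str = str(row[cols["ec"]])
        m = _EMBEDDED_EC.search(smiles)
        if m:
            ec_str = m.group(1)
            smiles = smiles[: m.start()] + smiles[m.end():]
        try:
            ec = parse_ec(ec_str)
            parse_reaction_smiles(smiles)
        except InputError as exc:
            logger.warning("skipping row %d: %s", i, exc)
            report.rejects.append((int(i), str(exc)))
            continue
        if ec.x == 7:
            report.n_class7 += 1
            continue
        source = str(row["source"]) if "source" in df.columns else default_source
        records.append(ReactionRecord(smiles, ec, source))
    report.n_kept = len(records)
    if not records:
        raise InputError(f"no usable records in {path}")
    return records


# --------------------------------------------------------------------------
# Cross-validation folds
# --------------------------------------------------------------------------

def make_cv_folds(
    records: Sequence[ReactionRecord],
    k: int,
    level: int = 1,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified k-fold (train, validation, test) index triples.

    Stratification is on the level-truncated EC label.  Labels with fewer
    than ``k`` members are scattered across test folds at random.  Within
    each training portion, ``val_fraction`` (default 10%) is held out as a
    stratified validation split.  Deterministic for a given seed.
    """
    n = len(records)
    if k < 2:
        raise InputError("k must be >= 2")
    if k > n:
        raise InputError(f"k={k} exceeds number of records ({n})")
    rng = np.random.default_rng(seed)
    labels = np.array([r.ec.truncate(level) for r in records])

    test_folds: list[list[int]] = [[] for _ in range(k)]
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        if len(idx) >= k:
            # deal round-robin starting at a random fold so fold sizes balance
            start = int(rng.integers(k))
            for j, i in enumerate(idx):
                test_folds[(start + j) % k].append(int(i))
        else:
            for i in idx:
                test_folds[int(rng.integers(k))].append(int(i))

    folds = []
    for f in range(k):
        test = np.array(sorted(test_folds[f]), dtype=int)
        pool = np.array(sorted(set(range(n)) - set(test)), dtype=int)
        # stratified validation carve-out from the training pool
        val: list[int] = []
        pool_labels = labels[pool]
        for lab in sorted(set(pool_labels)):
            lidx = pool[pool_labels == lab]
            if len(lidx) < 2:
                continue  # keep lone examples in training
            n_val = max(1, int(round(val_fraction * len(lidx))))
            picked = rng.choice(lidx, size=n_val, replace=False)
            val.extend(int(i) for i in picked)
        val_arr = np.array(sorted(val), dtype=int)
        train = np.array(sorted(set(pool) - set(val)), dtype=int)
        folds.append((train, val_arr, test))
    return folds


# --------------------------------------------------------------------------
# Fixture corpus
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureTemplate:
    """One pseudo-class: a diagnostic fragment molecule plus scaffold pool."""

    diagnostic: str
    scaffolds: tuple[str, ...]


@dataclass
class FixtureConfig:
    n_classes: int
    n_per_class: int
    seed: int
    templates: list[FixtureTemplate]
    # side-pools shared by all classes; they create uninformative
    # symmetric-difference fragments so the diagnostic bit is not the only
    # signal present, just the only class-correlated one
    cosubstrates: tuple[str, ...] = ("O", "CO", "N")
    byproducts: tuple[str, ...] = ("C=O", "OC=O", "CC#N")


_DIAGNOSTICS = ("ClC(Cl)Cl", "BrCCBr", "S=C=S", "FC(F)F", "ICI", "O=[Se]=O")

_SCAFFOLDS = (
    "CCO",
    "CC(C)O",
    "CCN",
    "CCCC",
    "CC(=O)OC",
    "OCC(O)CO",
    "CCOCC",
    "CC(N)C(=O)O",
)


def default_fixture_config(n_classes: int = 3, n_per_class: int = 10, seed: int = 0) -> FixtureConfig:
    if n_classes > len(_DIAGNOSTICS):
        raise ConfigError(f"at most {len(_DIAGNOSTICS)} built-in pseudo-classes")
    templates = [FixtureTemplate(_DIAGNOSTICS[c], _SCAFFOLDS) for c in range(n_classes)]
    return FixtureConfig(n_classes, n_per_class, seed, templates)


def _validate_fixture_config(config: FixtureConfig) -> None:
    if config.n_classes != len(config.templates):
        raise ConfigError("n_classes must match the number of templates")
    diags = [Chem.MolFromSmiles(t.diagnostic) for t in config.templates]
    if any(d is None for d in diags):
        raise ConfigError("invalid diagnostic SMILES in templates")
    for t, d in zip(config.templates, diags):
        for pool in (t.scaffolds, config.cosubstrates, config.byproducts):
            for s in pool:
                mol = Chem.MolFromSmiles(s)
                if mol is None:
                    raise ConfigError(f"invalid pool SMILES {s!r}")
                if mol.HasSubstructMatch(d):
                    raise ConfigError(
                        f"diagnostic fragment {t.diagnostic!r} occurs in pool molecule {s!r}"
                    )
    canon = [Chem.MolToSmiles(d) for d in diags]
    if len(set(canon)) != len(canon):
        raise ConfigError("diagnostic fragments must be pairwise distinct")
    for i, di in enumerate(diags):
        for j, dj in enumerate(diags):
            if i != j and dj.HasSubstructMatch(di):
                raise ConfigError(
                    "diagnostic fragment of one class occurs inside another class's diagnostic"
                )


def generate_fixture_corpus(config: FixtureConfig) -> list[ReactionRecord]:
    """Template reactions ``scaffold.cosubstrate >> scaffold.diagnostic.byproduct``.

    The scaffold appears unchanged on both sides, so its fragments cancel in
    the differential fingerprint; the class-c diagnostic molecule appears only
    in class-c products, guaranteeing a class-specific fragment in the
    symmetric difference.  Pseudo-EC labels are ``c.1.1``.
    """
    _validate_fixture_config(config)
    rng = np.random.default_rng(config.seed)
    records = []
    for c, template in enumerate(config.templates, start=1):
        for _ in range(config.n_per_class):
            scaffold = template.scaffolds[int(rng.integers(len(template.scaffolds)))]
            cosub = config.cosubstrates[int(rng.integers(len(config.cosubstrates)))]
            byprod = config.byproducts[int(rng.integers(len(config.byproducts)))]
            smiles = f"{scaffold}.{cosub}>>{scaffold}.{template.diagnostic}.{byprod}"
            records.append(ReactionRecord(smiles, parse_ec(f"{c}.1.1"), "fixture"))
    return records


def records_to_dataframe(records: Iterable[ReactionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rxn_smiles": [r.reaction_smiles for r in records],
            "ec": [r.ec.render() for r in records],
            "source": [r.source for r in records],
        }
    )


def records_to_csv(records: Iterable[ReactionRecord], path=None) -> str:
    """Dump records in the rhea_csv layout (plus source column)."""
    df = records_to_dataframe(records)
    if path is not None:
        df.to_csv(path, index=False)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()
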