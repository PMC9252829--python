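"""System-definition models and HMM metadata.

A system-definition model is a declarative rule set: the core gene families a
defence system requires, accessory families that may accompany them,
prohibited families incompatible with the classification, quorum counts
(minimum distinct core / total families) and a colocalization limit (maximum
number of intervening unrelated genes).  Models live one-per-file as YAML
under ``<db_dir>/sys/``; the HMM metadata table ``<db_dir>/hmm_meta.txt``
(TSV) maps each profile-HMM accession to the protein family it evidences and
to optional per-HMM score thresholds.

Non-protein components are referenced with the reserved family tokens
``ncRNA`` and ``CRISPR_array``; they are valid in any of the three family
lists and are never expected to have an evidencing HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: Family tokens that denote non-protein components (no HMM evidence).
NONPROTEIN_TOKENS = frozenset({"ncRNA", "CRISPR_array"})

#: Suffix marking relaxed catch-all models.
OTHER_SUFFIX = "_other"


class ModelValidationError(ValueError):
    """A system-definition file violates the model invariants."""


class ModelParseError(ValueError):
    """A system-definition file could not be parsed."""


@dataclass(frozen=True)
class SystemModel:
    """One declarative defence-system definition."""

    name: str
    family: str
    core_families: tuple[str, ...]
    accessory_families: tuple[str, ...] = ()
    prohibited_families: tuple[str, ...] = ()
    minimum_core: int = -1  # -1 → default: all core families
    minimum_total: int = -1  # -1 → default: minimum_core
    maximum_separation: int = -1  # -1 → global default at detection time

    def __post_init__(self) -> None:
        if self.minimum_core < 0:
            object.__setattr__(self, "minimum_core", len(self.core_families))
        if self.minimum_total < 0:
            object.__setattr__(self, "minimum_total", self.minimum_core)
        self.validate()

    def validate(self) -> None:
        if not self.name:
            raise ModelValidationError("model name must be non-empty")
        if not self.core_families:
            raise ModelValidationError(f"model {self.name!r}: no core families")
        core, acc, proh = (
            set(self.core_families),
            set(self.accessory_families),
            set(self.prohibited_families),
        )
        for a, b, la, lb in (
            (core, acc, "core", "accessory"),
            (core, proh, "core", "prohibited"),
            (acc, proh, "accessory", "prohibited"),
        ):
            common = a & b
            if common:
                raise ModelValidationError(
                    f"model {self.name!r}: families {sorted(common)} appear in both "
                    f"{la} and {lb} lists"
                )
        if self.minimum_core > len(core):
            raise ModelValidationError(
                f"model {self.name!r}: minimum_core {self.minimum_core} exceeds the "
                f"{len(core)} listed core families"
            )
        if self.minimum_total < self.minimum_core:
            raise ModelValidationError(
                f"model {self.name!r}: minimum_total {self.minimum_total} below "
                f"minimum_core {self.minimum_core}"
            )
        if self.maximum_separation < -1:
            raise ModelValidationError(
                f"model {self.name!r}: maximum_separation must be >= 0"
            )

    @property
    def is_other(self) -> bool:
        """Relaxed catch-all models are recognised by the ``_other`` name suffix."""
        return self.name.endswith(OTHER_SUFFIX)

    @property
    def member_families(self) -> frozenset[str]:
        """Families that count toward quorum (core + accessory)."""
        return frozenset(self.core_families) | frozenset(self.accessory_families)

    @property
    def relevant_families(self) -> frozenset[str]:
        """All families that anchor this model's candidate clusters."""
        return self.member_families | frozenset(self.prohibited_families)

    def separation(self, default: int) -> int:
        return self.maximum_separation if self.maximum_separation >= 0 else default


@dataclass(frozen=True)
class HmmMeta:
    """Metadata for one profile HMM: family joined to hits, per-HMM thresholds."""

    accession: str
    original_name: str
    protein_family: str
    evalue_max: float | None = None
    target_cov_min: float | None = None
    hmm_cov_min: float | None = None
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.protein_family:
            raise ModelValidationError(
                f"HMM {self.accession!r}: protein_family must be non-empty"
            )
        if self.evalue_max is not None and not math.isfinite(self.evalue_max):
            raise ModelValidationError(f"HMM {self.accession!r}: non-finite E-value threshold")
        for nm in ("target_cov_min", "hmm_cov_min"):
            v = getattr(self, nm)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ModelValidationError(
                    f"HMM {self.accession!r}: {nm} {v} outside [0, 1]"
                )


def _derive_family(name: str) -> str:
    """Grouping label for a model: the name with a trailing subtype token removed.

    ``DISARM_I`` → ``DISARM``; ``wadjet_other`` → ``wadjet``; ``retron`` → ``retron``.
    """
    if "_" in name:
        return name.rsplit("_", 1)[0]
    return name


_MODEL_KEYS = {
    "family",
    "core",
    "accessory",
    "prohibited",
    "minimum_core",
    "minimum_total",
    "maximum_separation",
}


def parse_model_file(path: Path) -> SystemModel:
    """Parse one YAML system-definition file into a :class:`SystemModel`.

    The model name is the file stem; the file holds flat keys ``core``,
    ``accessory``, ``prohibited`` (lists of family tokens) and integer
    ``minimum_core`` / ``minimum_total`` / ``maximum_separation``.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f", line {mark.line + 1}" if mark is not None else ""
        raise ModelParseError(f"{path}{line}: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelParseError(f"{path}: expected a key/value mapping")
    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ModelParseError(f"{path}: unknown keys {sorted(unknown)}")

    def _tokens(key: str) -> tuple[str, ...]:
        raw = data.get(key) or []
        if isinstance(raw, str):
            raw = [raw]
        if not isinstance(raw, list) or not all(isinstance(t, str) for t in raw):
            raise ModelParseError(f"{path}: {key!r} must be a list of family tokens")
        return tuple(raw)

    name = path.stem
    try:
        return SystemModel(
            name=name,
            family=str(data.get("family") or _derive_family(name)),
            core_families=_tokens("core"),
            accessory_families=_tokens("accessory"),
            prohibited_families=_tokens("prohibited"),
            minimum_core=int(data.get("minimum_core", -1)),
            minimum_total=int(data.get("minimum_total", -1)),
            maximum_separation=int(data.get("maximum_separation", -1)),
        )
    except ModelValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ModelParseError(f"{path}: {exc}") from exc


def load_models(db_dir: Path) -> list[SystemModel]:
    """Load every system-definition file under ``<db_dir>/sys``, sorted by name.

    Loading is order-independent: the result is sorted by model name so that
    any enumeration order of the directory yields an identical list.
    """
    sys_dir = Path(db_dir) / "sys"
    if not sys_dir.is_dir():
        raise FileNotFoundError(f"no 'sys' directory under {db_dir}")
    models = [
        parse_model_file(p)
        for p in sorted(sys_dir.iterdir())
        if p.suffix in {".yaml", ".yml"} and p.is_file()
    ]
    if not models:
        raise FileNotFoundError(f"no model files (*.yaml) under {sys_dir}")
    return sorted(models, key=lambda m: m.name)


#: Canonical hmm_meta.txt column names → HmmMeta fields.
_META_COLUMNS = {
    "accession": "accession",
    "original.name": "original_name",
    "protein.family": "protein_family",
    "e.val.threshold": "evalue_max",
    "target.coverage.threshold": "target_cov_min",
    "hmm.coverage.threshold": "hmm_cov_min",
    "citation": "citation",
}


def load_hmm_meta(path: Path) -> dict[str, HmmMeta]:
    """Load the TSV HMM metadata table, keyed by accession.

    Absent threshold cells (empty, ``NA`` or ``-``) mean "use the global
    default".  Unknown columns are ignored; several rows may share one
    protein family (families represented by multiple HMM clades).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA", "-"], keep_default_na=False)
    missing = {"accession", "protein.family"} - set(df.columns)
    if missing:
        raise ModelParseError(f"{path}: missing required columns {sorted(missing)}")
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise ModelParseError(f"{path}: duplicate accessions {sorted(dup.unique())}")

    meta: dict[str, HmmMeta] = {}
    for _, row in df.iterrows():
        fields: dict[str, object] = {}
        for col, attr in _META_COLUMNS.items():
            if col not in df.columns:
                continue
            val = row[col]
            if pd.isna(val):
                continue
            if attr in {"evalue_max", "target_cov_min", "hmm_cov_min"}:
                fields[attr] = float(val)
            else:
                fields[attr] = str(val)
        if "protein_family" not in fields or not fields["protein_family"]:
            raise ModelParseError(
                f"{path}: row {row['accession']!r} lacks a protein.family"
            )
        fields.setdefault("original_name", str(fields["accession"]))
        meta[str(row["accession"])] = HmmMeta(**fields)  # type: ignore[arg-type]
    return meta


def family_index(meta: dict[str, HmmMeta]) -> dict[str, list[str]]:
    """Map protein family → sorted accessions of the HMMs evidencing it."""
    idx: dict[str, list[str]] = {}
    for acc, m in meta.items():
        idx.setdefault(m.protein_family, []).append(acc)
    return {fam: sorted(accs) for fam, accs in idx.items()}


def cross_validate(models: list[SystemModel], meta: dict[str, HmmMeta]) -> list[str]:
    """Report (as warnings, not errors) model family tokens with no evidencing HMM.

    Non-protein tokens (``ncRNA``, ``CRISPR_array``) never need an HMM and are
    excluded.  Returns a sorted list of human-readable warning strings; an
    empty list means full coverage.
    """
    idx = family_index(meta)
    warnings: list[str] = []
    for model in models:
        for token in sorted(model.relevant_families - NONPROTEIN_TOKENS):
            if token not in idx:
                warnings.append(
                    f"model {model.name!r}: family token {token!r} has no evidencing HMM"
                )
    return sorted(set(warnings))


@dataclass
class ModelDatabase:
    """A loaded model database: system definitions + HMM metadata + HMM file path."""

    db_dir: Path
    models: list[SystemModel] = field(default_factory=list)
    meta: dict[str, HmmMeta] = field(default_factory=dict)

    @classmethod
    def load(cls, db_dir: Path) -> "ModelDatabase":
        db_dir = Path(db_dir)
        models = load_models(db_dir)
        meta_path = db_dir / "hmm_meta.txt"
        meta = load_hmm_meta(meta_path) if meta_path.exists() else {}
        return cls(db_dir=db_dir, models=models, meta=meta)

    @property
    def hmm_path(self) -> Path:
        """Concatenated HMMER3 text profiles of the database."""
        return Path(self.db_dir) / "hmm" / "profiles.hmm"

    def validate(self) -> list[str]:
        return cross_validate(self.models, self.meta)
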