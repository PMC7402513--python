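"""Input tables, dataset assembly and serialization.

The pipeline consumes six plain TSV tables (all with a header row; one row
per association for multi-valued fields):

================  ==========================  =================================
table             columns                     meaning
================  ==========================  =================================
fingerprints      drug_id, bitstring          binary molecular fingerprint
drug_targets      drug_id, protein_id         drug -> target protein
protein_go        protein_id, go_term         protein -> GO annotation
substituents      drug_id, substituent        drug -> substituent group
atc               drug_id, atc_code           drug -> 7-character WHO ATC code
dsp               drug_id, side_effect_id     known drug side-effect pair
================  ==========================  =================================

``assemble_dataset`` turns the raw tables into an aligned :class:`Dataset`:
drugs missing data for any enabled similarity channel are removed (mirroring
the curation rule that drugs without similarity information cannot be
scored), and side-effects left with too few positive drugs are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DrugProfile",
    "ProteinAnnotation",
    "Dataset",
    "AnnotationTables",
    "FilterReport",
    "ParseError",
    "SchemaError",
    "AssemblyError",
    "read_fingerprints",
    "write_fingerprints",
    "read_annotations",
    "read_association",
    "write_association",
    "assemble_dataset",
    "load_dataset",
    "write_dataset",
    "summary_from_counts",
    "fingerprints_from_smiles",
]

ATC_CODE_LENGTH = 7

TABLE_FILES = {
    "fingerprints": "fingerprints.tsv",
    "drug_targets": "drug_targets.tsv",
    "protein_go": "protein_go.tsv",
    "substituents": "substituents.tsv",
    "atc": "atc.tsv",
    "dsp": "dsp.tsv",
}


class ParseError(ValueError):
    """A table row could not be interpreted."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class AssemblyError(ValueError):
    """Dataset assembly produced an unusable dataset."""

    def __init__(self, message: str, report: "FilterReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class DrugProfile:
    """One drug's feature channels.

    fingerprint is an ordered 0/1 vector of dataset-wide length L; targets,
    substituents and atc_codes are identifier sets.  A set may be empty only
    when the corresponding similarity channel is disabled.
    """

    drug_id: str
    fingerprint: np.ndarray | None = None
    targets: frozenset = frozenset()
    substituents: frozenset = frozenset()
    atc_codes: frozenset = frozenset()


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    go_terms: frozenset


@dataclass
class AnnotationTables:
    """The five association tables, duplicates collapsed."""

    drug_targets: dict[str, frozenset]
    protein_go: dict[str, frozenset]
    substituents: dict[str, frozenset]
    atc: dict[str, frozenset]
    pairs: set[tuple[str, str]]


@dataclass
class FilterReport:
    """Audit trail for assembly: what was dropped and why."""

    drugs_in: int = 0
    drugs_kept: int = 0
    drugs_dropped: dict[str, int] = field(default_factory=dict)
    side_effects_in: int = 0
    side_effects_kept: int = 0
    side_effects_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "drugs_in": self.drugs_in,
            "drugs_kept": self.drugs_kept,
            "drugs_dropped": dict(self.drugs_dropped),
            "side_effects_in": self.side_effects_in,
            "side_effects_kept": self.side_effects_kept,
            "side_effects_dropped": self.side_effects_dropped,
        }


@dataclass
class Dataset:
    """Aligned drug profiles plus the drug x side-effect label matrix.

    Drugs and side-effects are ordered lexicographically by identifier and
    the ordering is frozen at assembly, so matrix indices are deterministic.
    labels[d, s] == 1 iff drug d is known to cause side-effect s; all other
    drugs are *unlabeled* for s (candidate negatives), not confirmed safe.
    """

    drugs: list[DrugProfile]
    proteins: dict[str, ProteinAnnotation]
    labels: np.ndarray
    side_effect_ids: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (len(self.drugs), len(self.side_effect_ids)):
            raise AssemblyError(
                f"label matrix shape {self.labels.shape} does not match "
                f"{len(self.drugs)} drugs x {len(self.side_effect_ids)} side-effects"
            )
        self._drug_index = {d.drug_id: i for i, d in enumerate(self.drugs)}
        self._se_index = {s: i for i, s in enumerate(self.side_effect_ids)}
        if len(self._drug_index) != len(self.drugs):
            raise AssemblyError("duplicate drug ids")

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_side_effects(self) -> int:
        return len(self.side_effect_ids)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def se_index(self, side_effect_id: str) -> int:
        try:
            return self._se_index[side_effect_id]
        except KeyError:
            raise KeyError(f"unknown side-effect id {side_effect_id!r}") from None

    def positives(self, side_effect_id: str) -> list[str]:
        """Drugs known to cause the side-effect, in index order."""
        col = self.labels[:, self.se_index(side_effect_id)]
        return [self.drugs[i].drug_id for i in np.flatnonzero(col)]

    def candidates(self, side_effect_id: str) -> list[str]:
        """Unlabeled drugs for the side-effect (candidate negatives)."""
        col = self.labels[:, self.se_index(side_effect_id)]
        return [self.drugs[i].drug_id for i in np.flatnonzero(col == 0)]

    def n_pairs(self) -> int:
        return int(self.labels.sum())

    def summary(self) -> dict:
        """Headline counts and the two per-entity averages."""
        return summary_from_counts(self.n_drugs, self.n_side_effects, self.n_pairs())

    def n_side_effects_more_unlabeled(self) -> int:
        """Side-effects with more unlabeled than labeled drugs (imbalance census)."""
        pos = self.labels.sum(axis=0)
        return int(np.sum(self.n_drugs - pos > pos))


def summary_from_counts(n_drugs: int, n_side_effects: int, n_pairs: int) -> dict:
    """Dataset summary arithmetic from headline counts alone."""
    return {
        "n_drugs": int(n_drugs),
        "n_side_effects": int(n_side_effects),
        "n_pairs": int(n_pairs),
        "avg_side_effects_per_drug": n_pairs / n_drugs if n_drugs else 0.0,
        "avg_drugs_per_side_effect": n_pairs / n_side_effects if n_side_effects else 0.0,
    }


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv_rows(path, expected_columns: tuple[str, ...]) -> list[list[str]]:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        return []
    header = lines[0].split("\t")
    if tuple(header[: len(expected_columns)]) != expected_columns:
        raise SchemaError(
            f"{path.name}: expected columns {list(expected_columns)}, got {header}"
        )
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) < len(expected_columns):
            raise ParseError(f"{path.name}:{lineno}: expected {len(expected_columns)} fields")
        rows.append(parts[: len(expected_columns)])
    return rows


def read_fingerprints(path, length: int) -> dict[str, np.ndarray]:
    """Read drug_id -> binary fingerprint vectors of exactly ``length`` bits."""
    out: dict[str, np.ndarray] = {}
    for lineno, (drug_id, bits) in enumerate(
        ((r[0], r[1]) for r in _read_tsv_rows(path, ("drug_id", "bitstring"))), start=2
    ):
        if len(bits) != length:
            raise ParseError(
                f"drug {drug_id!r} (line {lineno}): bitstring length {len(bits)} != {length}"
            )
        if set(bits) - {"0", "1"}:
            raise ParseError(f"drug {drug_id!r} (line {lineno}): bitstring not binary")
        out[drug_id] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return out


def write_fingerprints(path, fingerprints: Mapping[str, np.ndarray]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tbitstring\n")
        for drug_id in sorted(fingerprints):
            bits = "".join(str(int(b)) for b in fingerprints[drug_id])
            fh.write(f"{drug_id}\t{bits}\n")


def read_association(path, columns: tuple[str, str]) -> dict[str, frozenset]:
    """Read a two-column association table as key -> value-set (duplicates collapsed)."""
    assoc: dict[str, set] = {}
    for key, value in _read_tsv_rows(path, columns):
        assoc.setdefault(key, set()).add(value)
    return {k: frozenset(v) for k, v in assoc.items()}


def write_association(path, assoc: Mapping[str, Iterable[str]], columns: tuple[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for key in sorted(assoc):
            for value in sorted(assoc[key]):
                fh.write(f"{key}\t{value}\n")


def read_annotations(
    drug_target_path, protein_go_path, substituent_path, atc_path, dsp_path
) -> AnnotationTables:
    """Read the five association tables; duplicate rows collapse by set semantics."""
    pairs = {
        (d, s) for d, s in _read_tsv_rows(dsp_path, ("drug_id", "side_effect_id"))
    }
    return AnnotationTables(
        drug_targets=read_association(drug_target_path, ("drug_id", "protein_id")),
        protein_go=read_association(protein_go_path, ("protein_id", "go_term")),
        substituents=read_association(substituent_path, ("drug_id", "substituent")),
        atc=read_association(atc_path, ("drug_id", "atc_code")),
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Assembly

ALL_CHANNELS = ("chem", "tar", "sub", "thera")


def assemble_dataset(
    fingerprints: Mapping[str, np.ndarray],
    annotations: AnnotationTables,
    channels: Iterable[str] = ALL_CHANNELS,
    min_positives: int = 1,
) -> tuple[Dataset, FilterReport]:
    """Build an aligned dataset, filtering drugs that cannot be scored.

    A drug is retained only if it has data for every enabled channel:
    a fingerprint (chem), at least one target whose protein is annotated
    (tar), at least one substituent (sub), and at least one well-formed
    ATC code (thera).  Side-effects with fewer than ``min_positives``
    surviving positive drugs are dropped.  Raises :class:`AssemblyError`
    (carrying the filter report) if nothing survives.
    """
    channels = tuple(channels)
    unknown = set(channels) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    universe = set(annotations.drug_targets) | set(annotations.substituents)
    universe |= set(annotations.atc) | set(fingerprints)
    universe |= {d for d, _ in annotations.pairs}

    report = FilterReport(drugs_in=len(universe))
    dropped = {f"missing_{c}": 0 for c in channels}

    kept: list[str] = []
    for drug_id in sorted(universe):
        reason = None
        if "chem" in channels and drug_id not in fingerprints:
            reason = "missing_chem"
        elif "tar" in channels:
            targets = annotations.drug_targets.get(drug_id, frozenset())
            if not targets or any(t not in annotations.protein_go for t in targets):
                reason = "missing_tar"
        if reason is None and "sub" in channels and not annotations.substituents.get(drug_id):
            reason = "missing_sub"
        if reason is None and "thera" in channels:
            codes = annotations.atc.get(drug_id, frozenset())
            if not codes:
                reason = "missing_thera"
            else:
                bad = [c for c in codes if len(c) != ATC_CODE_LENGTH]
                if bad:
                    raise AssemblyError(
                        f"drug {drug_id!r}: malformed ATC code(s) {sorted(bad)} "
                        f"(expected {ATC_CODE_LENGTH} characters)"
                    )
        if reason is None:
            kept.append(drug_id)
        else:
            dropped[reason] += 1

    report.drugs_kept = len(kept)
    report.drugs_dropped = dropped
    if not kept:
        raise AssemblyError(f"no drugs survived filtering: {report.to_dict()}", report)

    kept_set = set(kept)
    se_positives: dict[str, set[str]] = {}
    for drug_id, se_id in annotations.pairs:
        if drug_id in kept_set:
            se_positives.setdefault(se_id, set()).add(drug_id)
    all_ses = sorted({s for _, s in annotations.pairs})
    report.side_effects_in = len(all_ses)
    se_ids = [s for s in all_ses if len(se_positives.get(s, ())) >= min_positives]
    report.side_effects_kept = len(se_ids)
    report.side_effects_dropped = len(all_ses) - len(se_ids)
    if not se_ids:
        raise AssemblyError(f"no side-effects survived filtering: {report.to_dict()}", report)

    drugs = [
        DrugProfile(
            drug_id=d,
            fingerprint=np.asarray(fingerprints[d], dtype=np.uint8) if d in fingerprints else None,
            targets=annotations.drug_targets.get(d, frozenset()),
            substituents=annotations.substituents.get(d, frozenset()),
            atc_codes=annotations.atc.get(d, frozenset()),
        )
        for d in kept
    ]
    proteins = {
        p: ProteinAnnotation(p, terms) for p, terms in annotations.protein_go.items()
    }
    labels = np.zeros((len(drugs), len(se_ids)), dtype=np.uint8)
    di = {d: i for i, d in enumerate(kept)}
    si = {s: i for i, s in enumerate(se_ids)}
    for drug_id, se_id in annotations.pairs:
        if drug_id in di and se_id in si:
            labels[di[drug_id], si[se_id]] = 1
    return Dataset(drugs=drugs, proteins=proteins, labels=labels, side_effect_ids=se_ids), report


def load_dataset(
    directory, channels: Iterable[str] = ALL_CHANNELS, fingerprint_length: int = 1024,
    min_positives: int = 1,
) -> tuple[Dataset, FilterReport]:
    """Read the six standard tables from a directory and assemble them."""
    directory = Path(directory)
    fps = {}
    if "chem" in channels:
        fps = read_fingerprints(directory / TABLE_FILES["fingerprints"], fingerprint_length)
    ann = read_annotations(
        directory / TABLE_FILES["drug_targets"],
        directory / TABLE_FILES["protein_go"],
        directory / TABLE_FILES["substituents"],
        directory / TABLE_FILES["atc"],
        directory / TABLE_FILES["dsp"],
    )
    return assemble_dataset(fps, ann, channels=channels, min_positives=min_positives)


def write_dataset(dataset: Dataset, directory) -> None:
    """Write a dataset back to the six standard tables (exact round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fps = {d.drug_id: d.fingerprint for d in dataset.drugs if d.fingerprint is not None}
    write_fingerprints(directory / TABLE_FILES["fingerprints"], fps)
    write_association(
        directory / TABLE_FILES["drug_targets"],
        {d.drug_id: d.targets for d in dataset.drugs if d.targets},
        ("drug_id", "protein_id"),
    )
    write_association(
        directory / TABLE_FILES["protein_go"],
        {p.protein_id: p.go_terms for p in dataset.proteins.values()},
        ("protein_id", "go_term"),
    )
    write_association(
        directory / TABLE_FILES["substituents"],
        {d.drug_id: d.substituents for d in dataset.drugs if d.substituents},
        ("drug_id", "substituent"),
    )
    write_association(
        directory / TABLE_FILES["atc"],
        {d.drug_id: d.atc_codes for d in dataset.drugs if d.atc_codes},
        ("drug_id", "atc_code"),
    )
    with open(directory / TABLE_FILES["dsp"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tside_effect_id\n")
        for i, drug in enumerate(dataset.drugs):
            for j in np.flatnonzero(dataset.labels[i]):
                fh.write(f"{drug.drug_id}\t{dataset.side_effect_ids[j]}\n")
    with open(directory / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(dataset.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def fingerprints_from_smiles(path, length: int = 1024) -> dict[str, np.ndarray]:
    """Optional adapter: compute topological fingerprints from a SMILES file.

    The file holds one record per line: ``drug_id<TAB>SMILES``.  Requires
    RDKit.  Precomputed bit tables (``read_fingerprints``) are the reference
    input path; fingerprints from different toolkits are not bit-compatible,
    so mixing backends within one dataset is not supported.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SMILES fingerprinting requires the rdkit extra") from exc

    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=length)
    out: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln:
                continue
            drug_id, smiles = ln.split("\t")[:2]
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ParseError(f"drug {drug_id!r} (line {lineno}): invalid SMILES")
            fp = gen.GetFingerprint(mol)
            out[drug_id] = np.array(fp, dtype=np.uint8)
    return out
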