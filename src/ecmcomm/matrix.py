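"""Sample-by-species presence/absence matrices with habitat/forest labels."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ecmcomm.errors import FormatError, ValidationError

_META_COLS = ("forest", "habitat")


@dataclass
class CommunityMatrix:
    """Binary incidence of species (columns) across samples (rows).

    Identifiers are case-sensitive and whitespace-trimmed.  Every species
    must be present in at least one sample; cells are strictly 0/1.
    """

    sample_ids: list[str]
    species_ids: list[str]
    data: np.ndarray
    forests: list[str] | None = None
    habitats: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [s.strip() for s in self.sample_ids]
        self.species_ids = [s.strip() for s in self.species_ids]
        self.data = np.asarray(self.data, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.species_ids)
        if self.data.shape != (n, m):
            raise ValidationError(
                f"matrix shape {self.data.shape} does not match {n} samples x {m} species"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.species_ids)) != m:
            raise ValidationError("duplicate species ids")
        if not np.isin(self.data, (0, 1)).all():
            raise ValidationError("matrix cells must be 0 or 1")
        if m and (self.data.sum(axis=0) == 0).any():
            empty = [
                sp for sp, tot in zip(self.species_ids, self.data.sum(axis=0)) if tot == 0
            ]
            raise ValidationError(f"species present in no sample: {empty}")
        for name, labels in (("forests", self.forests), ("habitats", self.habitats)):
            if labels is not None and len(labels) != n:
                raise ValidationError(f"{name} labels must match sample count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def species_present(self) -> list[str]:
        return [sp for sp, tot in zip(self.species_ids, self.data.sum(axis=0)) if tot > 0]

    def sample_species(self, sample_id: str) -> list[str]:
        i = self.sample_ids.index(sample_id)
        return [sp for sp, v in zip(self.species_ids, self.data[i]) if v]

    def subset_samples(self, keep: list[str]) -> "CommunityMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        data = self.data[idx]
        present = data.sum(axis=0) > 0
        return CommunityMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            species_ids=[sp for sp, p in zip(self.species_ids, present) if p],
            data=data[:, present],
            forests=[self.forests[i] for i in idx] if self.forests else None,
            habitats=[self.habitats[i] for i in idx] if self.habitats else None,
        )


def concat_matrices(a: CommunityMatrix, b: CommunityMatrix) -> CommunityMatrix:
    """Stack two matrices over the union of their species columns."""
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValidationError(f"duplicate sample ids across matrices: {sorted(overlap)}")
    species = list(a.species_ids) + [s for s in b.species_ids if s not in a.species_ids]
    out = np.zeros((len(a.sample_ids) + len(b.sample_ids), len(species)), dtype=np.int8)
    col = {sp: j for j, sp in enumerate(species)}
    for j, sp in enumerate(a.species_ids):
        out[: len(a.sample_ids), col[sp]] = a.data[:, j]
    for j, sp in enumerate(b.species_ids):
        out[len(a.sample_ids):, col[sp]] = b.data[:, j]

    def _merge(x, y, n_a, n_b):
        if x is None and y is None:
            return None
        return list(x or ["" for _ in range(n_a)]) + list(y or ["" for _ in range(n_b)])

    return CommunityMatrix(
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        species_ids=species,
        data=out,
        forests=_merge(a.forests, b.forests, len(a.sample_ids), len(b.sample_ids)),
        habitats=_merge(a.habitats, b.habitats, len(a.sample_ids), len(b.sample_ids)),
    )


def read_matrix(path: str | Path) -> CommunityMatrix:
    """Read a tab-separated presence/absence matrix.

    First column is the sample id; optional metadata columns named
    ``forest`` and ``habitat`` may follow; remaining columns are species.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration as exc:
            raise FormatError(f"{path}: empty matrix file") from exc
        meta_idx = {
            name: header.index(name) for name in _META_COLS if name in header
        }
        species_cols = [
            j for j in range(1, len(header)) if j not in meta_idx.values()
        ]
        species = [header[j].strip() for j in species_cols]
        sample_ids: list[str] = []
        forests: list[str] = []
        habitats: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            sid = row[0].strip()
            if sid in sample_ids:
                raise FormatError(f"{path}: line {lineno}: duplicate sample id {sid!r}")
            sample_ids.append(sid)
            if "forest" in meta_idx:
                forests.append(row[meta_idx["forest"]].strip())
            if "habitat" in meta_idx:
                habitats.append(row[meta_idx["habitat"]].strip())
            vals: list[int] = []
            for j, col in zip(species_cols, species):
                cell = row[j].strip()
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"{path}: line {lineno}, species {col!r}: "
                        f"non-binary cell {cell!r}"
                    )
                vals.append(int(cell))
            rows.append(vals)
    try:
        return CommunityMatrix(
            sample_ids=sample_ids,
            species_ids=species,
            data=np.array(rows, dtype=np.int8).reshape(len(sample_ids), len(species)),
            forests=forests or None,
            habitats=habitats or None,
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: CommunityMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = ["sample"]
        if matrix.forests is not None:
            header.append("forest")
        if matrix.habitats is not None:
            header.append("habitat")
        header.extend(matrix.species_ids)
        fh.write("\t".join(header) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            row = [sid]
            if matrix.forests is not None:
                row.append(matrix.forests[i])
            if matrix.habitats is not None:
                row.append(matrix.habitats[i])
            row.extend(str(int(v)) for v in matrix.data[i])
            fh.write("\t".join(row) + "\n")
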