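"""Virtual screening: rank a library against an exemplar, retain the best.

Each library molecule is reduced to a pharmacophore model, rigidly aligned
to the exemplar, and scored by the volumetric Tanimoto; the ranked list keeps
every scorable molecule and flags the top-N as retained (default 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .exemplar import Exemplar
from .molio import LibraryEntry
from .pharmacophore import (
    AlignmentResult,
    FeaturelessMoleculeError,
    align,
    featurize_molecule,
    model_from_exemplar,
)

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 50  # retained best-aligned molecules per exemplar


class EmptyScreenError(ValueError):
    """Every library entry was featureless."""


@dataclass
class ScreenResult:
    site_label: str
    ranked: list[tuple[str, float, AlignmentResult]]
    retained_n: int
    skipped: list[str]

    def retained_ids(self) -> list[str]:
        return [r[0] for r in self.ranked[: self.retained_n]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "id": mol_id,
                "tanimoto": score,
                "retained": int(i < self.retained_n),
            }
            for i, (mol_id, score, _) in enumerate(self.ranked)
        ]
        return pd.DataFrame(rows, columns=["rank", "id", "tanimoto", "retained"])


def lead_like(entry: LibraryEntry) -> bool:
    """ZINC-style lead-like window: 250 ≤ MW ≤ 350 Da, logP ≤ 3.5, ≤7 rotatable bonds."""
    mol = entry.mol
    mw = entry.mol_weight or Descriptors.MolWt(mol)
    return (
        250.0 <= mw <= 350.0
        and Crippen.MolLogP(mol) <= 3.5
        and Lipinski.NumRotatableBonds(mol) <= 7
    )


def screen_library(
    exemplar: Exemplar,
    library: list[LibraryEntry],
    top_n: int = DEFAULT_TOP_N,
    seed: int = 0,
    n_starts: int = 6,
    lead_like_filter: bool = False,
    chunk_size: int = 1000,
    align_maxiter: int = 40,
) -> ScreenResult:
    """Featurize, align and rank every library entry against the exemplar.

    Featureless entries are skipped with a warning.  Ties in Tanimoto break
    by id ascending.  Deterministic for a fixed seed (each entry's alignment
    seed derives from (seed, library position)).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not library:
        raise ValueError("library is empty")
    target = model_from_exemplar(exemplar)
    scored: list[tuple[str, float, AlignmentResult]] = []
    skipped: list[str] = []
    entries = list(enumerate(library))
    for chunk_start in range(0, len(entries), chunk_size):
        chunk = entries[chunk_start : chunk_start + chunk_size]
        for idx, entry in chunk:
            if lead_like_filter and not lead_like(entry):
                skipped.append(entry.id)
                continue
            try:
                model = featurize_molecule(entry.mol, mol_id=entry.id)
            except FeaturelessMoleculeError:
                logger.warning("skipping featureless molecule %s", entry.id)
                skipped.append(entry.id)
                continue
            entry_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
            result = align(
                model, target, n_starts=n_starts, seed=entry_seed, maxiter=align_maxiter
            )
            scored.append((entry.id, result.tanimoto, result))
        logger.info("screened %d / %d", min(chunk_start + chunk_size, len(entries)), len(entries))
    if not scored:
        raise EmptyScreenError("no library entry produced pharmacophore features")
    scored.sort(key=lambda r: (-r[1], r[0]))
    return ScreenResult(
        site_label=exemplar.site_label,
        ranked=scored,
        retained_n=min(top_n, len(scored)),
        skipped=skipped,
    )


def _fingerprint(mol: Chem.Mol):
    # path-based hashed fingerprint, 2048 bits (documented default)
    return Chem.RDKFingerprint(mol, fpSize=2048)


def similarity_expand(
    query: LibraryEntry, library: list[LibraryEntry], threshold: float
) -> list[tuple[LibraryEntry, float]]:
    """Entries whose 2-D fingerprint Tanimoto to the query ≥ threshold,
    sorted by similarity descending (ties by id)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    qfp = _fingerprint(query.mol)
    hits = []
    for entry in library:
        sim = DataStructs.TanimotoSimilarity(qfp, _fingerprint(entry.mol))
        if sim >= threshold:
            hits.append((entry, float(sim)))
    hits.sort(key=lambda h: (-h[1], h[0].id))
    return hits


def diversity_pick(
    entries: list[LibraryEntry], n: int, max_pairwise: float = 0.7
) -> list[LibraryEntry]:
    """Greedy diversity selection: accept entries in order unless their 2-D
    similarity to an already-picked entry exceeds ``max_pairwise``."""
    picked: list[LibraryEntry] = []
    fps = []
    for entry in entries:
        fp = _fingerprint(entry.mol)
        if all(DataStructs.TanimotoSimilarity(fp, f) <= max_pairwise for f in fps):
            picked.append(entry)
            fps.append(fp)
        if len(picked) >= n:
            break
    return picked
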