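"""Similarity-profile features for drug pairs.

Each drug is described by three sets of binary descriptor tokens
(chemical substructures, protein targets, metabolizing enzymes).  A
drug's feature representation is its vector of Jaccard similarities to
every drug on a fixed roster, one column per modality, giving an
``n_drugs x 3`` profile matrix.  A drug pair is the ordered stack of the
two profile matrices, shape ``2 x n_drugs x 3``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The three descriptor modalities, in canonical order.
MODALITIES: tuple[str, ...] = ("substructure", "target", "enzyme")


class FeatureError(ValueError):
    """Raised for malformed descriptors, rosters or profile inputs."""


@dataclass(frozen=True)
class DrugDescriptorSet:
    """Per-drug descriptor token sets, one finite set per modality.

    Parameters
    ----------
    drug_id
        Unique identifier within a roster.
    modality_tokens
        Mapping from modality name (exactly the three in
        :data:`MODALITIES`) to a set of descriptor token strings.
        Token sets may be empty.
    """

    drug_id: str
    modality_tokens: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        keys = set(self.modality_tokens)
        if keys != set(MODALITIES):
            raise FeatureError(
                f"drug {self.drug_id!r}: modalities must be exactly "
                f"{sorted(MODALITIES)}, got {sorted(keys)}"
            )
        object.__setattr__(
            self,
            "modality_tokens",
            {m: frozenset(self.modality_tokens[m]) for m in MODALITIES},
        )

    def tokens(self, modality: str) -> frozenset[str]:
        if modality not in self.modality_tokens:
            raise FeatureError(f"unknown modality {modality!r}")
        return self.modality_tokens[modality]


@dataclass(frozen=True)
class DrugRoster:
    """An ordered roster of drugs plus per-modality token vocabularies.

    Drug order is canonical (sorted by ``drug_id``) and vocabularies are
    sorted unions of the tokens seen, so every derived feature matrix is
    reproducible across runs and machines.
    """

    drugs: tuple[DrugDescriptorSet, ...]
    vocab: Mapping[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [d.drug_id for d in self.drugs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FeatureError(f"duplicate drug ids in roster: {dupes}")
        if len(ids) < 2:
            raise FeatureError("a roster needs at least 2 drugs")
        ordered = tuple(sorted(self.drugs, key=lambda d: d.drug_id))
        object.__setattr__(self, "drugs", ordered)
        vocab = {
            m: tuple(sorted(set().union(*(d.tokens(m) for d in ordered))))
            for m in MODALITIES
        }
        object.__setattr__(self, "vocab", vocab)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(d.drug_id for d in self.drugs)

    def __getitem__(self, drug_id: str) -> DrugDescriptorSet:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)


@dataclass(frozen=True)
class FeatureProfileStack:
    """A drug's ``n_drugs x 3`` matrix of Jaccard similarities.

    Entry ``(j, m)`` is the Jaccard similarity between this drug and
    roster drug ``j`` in modality ``m``; all entries lie in [0, 1] and
    the drug's own row is 1.0 in every modality.
    """

    drug_id: str
    profile: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != len(MODALITIES):
            raise FeatureError(
                f"profile must be n_drugs x {len(MODALITIES)}, got shape {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise FeatureError("profile entries must lie in [0, 1]")
        object.__setattr__(self, "profile", p)


@dataclass(frozen=True)
class PairInput:
    """Ordered pair of profile matrices; the model input ``2 x n x 3``."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.shape != b.shape:
            raise FeatureError(f"pair shape mismatch: {a.shape} vs {b.shape}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (2,) + self.a.shape


@dataclass(frozen=True)
class PairSample:
    """An ordered (drug A, drug B, event label) record."""

    drug_a: str
    drug_b: str
    event: int


_warned_both_empty = False


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity |A∩B| / |A∪B| between two finite token sets.

    Two empty sets are treated as indistinguishable and score 1.0 (this
    avoids 0/0 for drugs with no annotation in a modality); a warning is
    emitted the first time that convention is used.
    """
    global _warned_both_empty
    sa, sb = set(a), set(b)
    if not sa and not sb:
        if not _warned_both_empty:
            warnings.warn(
                "Jaccard of two empty token sets defined as 1.0",
                RuntimeWarning,
                stacklevel=2,
            )
            _warned_both_empty = True
        return 1.0
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


def encode_onehot(
    drug: DrugDescriptorSet, vocab: Sequence[str], modality: str
) -> np.ndarray:
    """One-hot encode one modality of a drug against a token vocabulary.

    Element ``i`` is 1 iff ``vocab[i]`` is in the drug's token set for
    that modality.
    """
    tokens = drug.tokens(modality)
    vocab_set = set(vocab)
    missing = sorted(tokens - vocab_set)
    if missing:
        raise FeatureError(
            f"drug {drug.drug_id!r}, modality {modality!r}: tokens not in "
            f"vocabulary: {missing}"
        )
    return np.fromiter((1 if t in tokens else 0 for t in vocab), dtype=np.int8)


def _modality_similarity_matrix(roster: DrugRoster, modality: str) -> np.ndarray:
    """All-pairs Jaccard matrix for one modality, via binary linear algebra."""
    vocab = roster.vocab[modality]
    n = roster.n_drugs
    if not vocab:  # every set empty: all pairs indistinguishable
        jaccard(frozenset(), frozenset())  # trigger the convention warning once
        return np.ones((n, n))
    x = np.stack([encode_onehot(d, vocab, modality) for d in roster.drugs]).astype(
        np.float64
    )
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    both_empty = union == 0
    if both_empty.any():
        jaccard(frozenset(), frozenset())
    sim = np.where(both_empty, 1.0, inter / np.where(both_empty, 1.0, union))
    return sim


def similarity_matrices(roster: DrugRoster) -> dict[str, np.ndarray]:
    """Per-modality ``n_drugs x n_drugs`` Jaccard similarity matrices."""
    return {m: _modality_similarity_matrix(roster, m) for m in MODALITIES}


def build_profiles(roster: DrugRoster) -> list[FeatureProfileStack]:
    """Build the similarity-profile stack of every roster drug.

    Deterministic given the roster (which is itself canonically
    ordered); entry ``(j, m)`` of drug ``i``'s profile equals
    ``jaccard(tokens_i[m], tokens_j[m])``.
    """
    sims = similarity_matrices(roster)
    stacked = np.stack([sims[m] for m in MODALITIES], axis=-1)  # n x n x 3
    return [
        FeatureProfileStack(drug_id=d.drug_id, profile=stacked[i])
        for i, d in enumerate(roster.drugs)
    ]


def featurize_query(
    drug: DrugDescriptorSet, roster: DrugRoster
) -> FeatureProfileStack:
    """Featurize a drug (possibly absent from the roster) against the roster.

    The transductive convention: features are always similarities to the
    training roster's drugs, whether or not the query drug is on it.
    """
    profile = np.empty((roster.n_drugs, len(MODALITIES)))
    for m_idx, m in enumerate(MODALITIES):
        mine = drug.tokens(m)
        for j, other in enumerate(roster.drugs):
            profile[j, m_idx] = jaccard(mine, other.tokens(m))
    return FeatureProfileStack(drug_id=drug.drug_id, profile=profile)


def assemble_pair(a: FeatureProfileStack, b: FeatureProfileStack) -> PairInput:
    """Stack two profile matrices into an ordered model input."""
    if a.profile.shape != b.profile.shape:
        raise FeatureError(
            f"profile shape mismatch: {a.profile.shape} vs {b.profile.shape}"
        )
    return PairInput(a=a.profile.copy(), b=b.profile.copy())


def pairs_to_tensors(
    roster: DrugRoster, pairs: Sequence["PairSample"]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Featurize pair samples into model tensors.

    Returns ``(xa, xb, labels)`` with ``xa``/``xb`` of shape
    ``(n_pairs, n_drugs, 3)`` and integer event labels, preserving the
    input pair order.
    """
    profiles = {p.drug_id: p.profile for p in build_profiles(roster)}
    unknown = sorted(
        ({s.drug_a for s in pairs} | {s.drug_b for s in pairs}) - set(profiles)
    )
    if unknown:
        raise FeatureError(f"pair drugs absent from roster: {unknown}")
    xa = np.stack([profiles[s.drug_a] for s in pairs])
    xb = np.stack([profiles[s.drug_b] for s in pairs])
    labels = np.array([s.event for s in pairs], dtype=int)
    return xa, xb, labels


# ---------------------------------------------------------------------------
# I/O: long-format descriptor CSV / JSON, profile export
# ---------------------------------------------------------------------------

def read_descriptors_csv(path: str | Path) -> DrugRoster:
    """Read a long-format descriptor table: columns drug_id, modality, token.

    A drug may have zero rows for a modality (an empty set); a drug must
    appear in at least one row to be on the roster.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"drug_id", "modality", "token"}
    if not required.issubset(df.columns):
        raise FeatureError(
            f"descriptor CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = sorted(set(df["modality"]) - set(MODALITIES) - {""})
    if bad:
        raise FeatureError(f"unknown modalities in descriptor CSV: {bad}")
    drugs = []
    for drug_id, grp in df.groupby("drug_id", sort=True):
        tokens = {m: frozenset() for m in MODALITIES}
        for m, sub in grp.groupby("modality"):
            if m:
                tokens[m] = frozenset(t for t in sub["token"] if t)
        drugs.append(DrugDescriptorSet(drug_id=str(drug_id), modality_tokens=tokens))
    return DrugRoster(drugs=tuple(drugs))


def read_descriptors_json(path: str | Path) -> DrugRoster:
    """Read descriptors as JSON ``{drug_id: {modality: [tokens]}}``."""
    with open(path) as fh:
        data = json.load(fh)
    drugs = tuple(
        DrugDescriptorSet(
            drug_id=str(did),
            modality_tokens={m: frozenset(mod.get(m, [])) for m in MODALITIES},
        )
        for did, mod in data.items()
    )
    return DrugRoster(drugs=drugs)


def write_descriptors_csv(roster: DrugRoster, path: str | Path) -> None:
    rows = [
        {"drug_id": d.drug_id, "modality": m, "token": t}
        for d in roster.drugs
        for m in MODALITIES
        for t in sorted(d.tokens(m))
    ]
    pd.DataFrame(rows, columns=["drug_id", "modality", "token"]).to_csv(
        path, index=False
    )


def write_profile_matrices(roster: DrugRoster, out_dir: str | Path) -> dict[str, Path]:
    """Export per-modality similarity matrices as dense CSV with id headers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sims = similarity_matrices(roster)
    ids = list(roster.drug_ids)
    paths = {}
    for m in MODALITIES:
        p = out_dir / f"profile_{m}.csv"
        pd.DataFrame(sims[m], index=ids, columns=ids).to_csv(p, index_label="drug_id")
        paths[m] = p
    return paths
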