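"""Frequency-based substructure vocabulary (ESPF) and atom-aligned tokenizer.

SMILES are decomposed into *atom-level units* — one unit per atom token,
with bond symbols, ring-closure digits and branch parentheses attached to
the preceding atom's unit for bookkeeping.  A byte-pair-style procedure then
repeatedly merges the most frequent adjacent unit pair observed in a corpus,
yielding a vocabulary of recurring SMILES fragments.  Because every base
unit covers exactly one atom, each fragment of a tokenized molecule maps to
a definite atom-index set: these sets partition the molecule's atoms and are
the alignment key used to perturb the same substructure consistently across
the 1D sequence, the 2D graph and the 3D conformer.

Atom indices refer to the atom order of ``Chem.MolFromSmiles(input_smiles)``
(the package-wide indexing), even though the segmentation itself runs on the
canonical SMILES string.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .errors import ConfigurationError, InputError

__all__ = [
    "SubstructureVocab",
    "TokenizedMolecule",
    "atom_units",
    "build_vocab",
    "tokenize",
    "atoms_of_substructures",
]

# atom tokens inside a SMILES string: bracket atoms, two-letter halogens,
# organic-subset elements, aromatic lowercase
_ATOM_RE = re.compile(r"\[[^\]]+\]|Cl|Br|[BCNOPSFI]|[bcnops]")


def atom_units(smiles: str) -> tuple[list[str], list[int], str]:
    """Split a SMILES into atom-level units.

    Returns ``(units, unit_atom_index, canonical_smiles)`` where unit k is a
    substring of the canonical SMILES containing exactly one atom token, and
    ``unit_atom_index[k]`` is that atom's index in the *input* molecule's
    atom order.  Non-atom characters are attached to the preceding atom's
    unit (leading ones to the first atom's unit).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InputError(f"invalid SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    order = json.loads(mol.GetProp("_smilesAtomOutputOrder"))

    spans = [m.span() for m in _ATOM_RE.finditer(canonical)]
    if len(spans) != mol.GetNumAtoms():
        raise InputError(
            f"cannot align SMILES text to atoms for {canonical!r} "
            f"({len(spans)} atom tokens vs {mol.GetNumAtoms()} atoms)"
        )
    # unit k spans from its atom token start to the next atom token start;
    # any prefix before the first atom folds into unit 0
    units = []
    for k, (start, _) in enumerate(spans):
        begin = 0 if k == 0 else start
        end = spans[k + 1][0] if k + 1 < len(spans) else len(canonical)
        units.append(canonical[begin:end])
    return units, [int(i) for i in order], canonical


@dataclass
class SubstructureVocab:
    """A learned substructure vocabulary: base units plus ordered merges."""

    base_tokens: list[str]
    merges: list[tuple[str, str, str, int]]  # (left, right, merged, frequency)
    token_to_id: dict[str, int] = field(default_factory=dict)
    special_ids: dict[str, int] = field(default_factory=dict)
    fingerprint: str = ""

    SPECIALS = ("mask", "pad", "unknown")

    def __post_init__(self):
        if not self.token_to_id:
            self.special_ids = {name: i for i, name in enumerate(self.SPECIALS)}
            nxt = len(self.SPECIALS)
            for tok in self.base_tokens:
                self.token_to_id[tok] = nxt
                nxt += 1
            for _, _, merged, _ in self.merges:
                if merged not in self.token_to_id:
                    self.token_to_id[merged] = nxt
                    nxt += 1
        if not self.fingerprint:
            self.fingerprint = self._hash()

    def _hash(self) -> str:
        payload = json.dumps(
            {"base": self.base_tokens, "merges": self.merges, "specials": self.special_ids},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def mask_id(self) -> int:
        return self.special_ids["mask"]

    @property
    def pad_id(self) -> int:
        return self.special_ids["pad"]

    @property
    def unknown_id(self) -> int:
        return self.special_ids["unknown"]

    def __len__(self) -> int:
        return len(self.token_to_id) + len(self.special_ids)

    @property
    def n_ids(self) -> int:
        """Total id space (specials + substructure tokens)."""
        return len(self.special_ids) + len(self.token_to_id)

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unknown_id)

    # -- persistence: TSV with commented header, bit-exact reload -----------
    def save(self, path: str | Path) -> None:
        lines = ["#molclsp-espf-vocab\tv1"]
        lines.append("#fingerprint\t" + self.fingerprint)
        lines.append("#specials\t" + json.dumps(self.special_ids))
        lines.append("#base\t" + json.dumps(self.base_tokens))
        lines.append("rank\tleft\tright\tmerged\tfrequency")
        for rank, (l, r, m, f) in enumerate(self.merges):
            lines.append(f"{rank}\t{l}\t{r}\t{m}\t{f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SubstructureVocab":
        lines = Path(path).read_text().splitlines()
        header = {}
        rows = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                header[key] = val
            elif line and not line.startswith("rank\t"):
                rows.append(line.split("\t"))
        base = json.loads(header["base"])
        merges = [(l, r, m, int(f)) for _, l, r, m, f in rows]
        vocab = cls(base_tokens=base, merges=merges)
        if vocab.fingerprint != header.get("fingerprint"):
            raise InputError(f"vocabulary file {path} is corrupt (fingerprint mismatch)")
        return vocab


@dataclass
class TokenizedMolecule:
    """A SMILES segmented into substructure fragments aligned to atoms."""

    fragments: list[str]
    token_ids: list[int]
    atom_sets: list[frozenset[int]]
    n_atoms: int

    @property
    def e(self) -> int:
        return len(self.fragments)

    def validate(self) -> None:
        if not (len(self.fragments) == len(self.token_ids) == len(self.atom_sets)):
            raise InputError("tokenization fields have inconsistent lengths")
        union: set[int] = set()
        for s in self.atom_sets:
            if union & s:
                raise InputError("atom sets are not disjoint")
            union |= s
        if union != set(range(self.n_atoms)):
            raise InputError("atom sets do not cover all atoms")


def build_vocab(
    corpus: list[str], min_frequency: int = 2, max_size: int = 2048
) -> SubstructureVocab:
    """Learn a substructure vocabulary by iterative pair merging.

    Starting from atom-level units, the most frequent adjacent pair with
    corpus frequency >= `min_frequency` is merged each round (ties: higher
    frequency first, then lexicographically smaller merged string) until no
    pair qualifies or the vocabulary reaches `max_size` substructure tokens.
    The result depends only on corpus *content*, not its order.
    """
    if not corpus:
        raise InputError("empty corpus")
    if min_frequency < 1 or max_size < 1:
        raise ConfigurationError("min_frequency and max_size must be positive")

    sequences = [atom_units(s)[0] for s in corpus]
    base_tokens = sorted({u for seq in sequences for u in seq})
    merges: list[tuple[str, str, str, int]] = []
    vocab_size = len(base_tokens)

    while vocab_size < max_size:
        pairs: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                pairs[(a, b)] += 1
        if not pairs:
            break
        best = min(pairs.items(), key=lambda kv: (-kv[1], kv[0][0] + kv[0][1]))
        (left, right), freq = best
        if freq < min_frequency:
            break
        merged = left + right
        merges.append((left, right, merged, freq))
        sequences = [_merge_pair(seq, left, right, merged) for seq in sequences]
        if merged not in base_tokens:
            vocab_size += 1

    return SubstructureVocab(base_tokens=base_tokens, merges=merges)


def _merge_pair(seq: list[str], left: str, right: str, merged: str) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == left and seq[i + 1] == right:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def tokenize(smiles: str, vocab: SubstructureVocab) -> TokenizedMolecule:
    """Segment a SMILES into vocabulary fragments with their atom-index sets.

    The learned merges are replayed in order on the molecule's unit
    sequence; units that never merged and are absent from the vocabulary map
    to the unknown id (their singleton atom set is kept, so the atom
    partition invariant always holds).
    """
    units, atom_of_unit, _ = atom_units(smiles)
    seqs: list[tuple[str, frozenset[int]]] = [
        (u, frozenset({a})) for u, a in zip(units, atom_of_unit)
    ]
    for left, right, merged, _ in vocab.merges:
        out: list[tuple[str, frozenset[int]]] = []
        i = 0
        while i < len(seqs):
            if i + 1 < len(seqs) and seqs[i][0] == left and seqs[i + 1][0] == right:
                out.append((merged, seqs[i][1] | seqs[i + 1][1]))
                i += 2
            else:
                out.append(seqs[i])
                i += 1
        seqs = out

    tok = TokenizedMolecule(
        fragments=[f for f, _ in seqs],
        token_ids=[vocab.id_of(f) for f, _ in seqs],
        atom_sets=[s for _, s in seqs],
        n_atoms=len(units),
    )
    tok.validate()
    return tok


def atoms_of_substructures(tok: TokenizedMolecule, indices: set[int]) -> set[int]:
    """Union of the atom-index sets of the selected substructures."""
    bad = [i for i in indices if not (0 <= i < tok.e)]
    if bad:
        raise InputError(f"substructure indices out of range [0,{tok.e}): {sorted(bad)}")
    out: set[int] = set()
    for i in indices:
        out |= tok.atom_sets[i]
    return out
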