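"""SMILES tokenization and fixed-length index encoding for sequence models.

Tokens are atoms (two-letter halogens and bracket atoms are single tokens),
bonds, ring-bond digits (including %nn), branches and the dot separator.
Sequences are wrapped in GO/END control tokens and padded with a blank token
to a fixed length; decoding is the exact inverse on in-vocabulary strings.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("molgrow")

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d\d|[BCNOSPFIbcnops]|[0-9]|[=#\-\+\\/\(\)\.\*:~@])"
)

#: Frozen default token list covering common drug-like SMILES; the corpus
#: vocabulary is the union of this list and the tokens observed in the data.
DEFAULT_TOKENS: tuple[str, ...] = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I", "B",
    "b", "p", "1", "2", "3", "4", "5", "6", "7", "8", "9", "0", "(", ")",
    "=", "#", "-", "/", "\\", ".", "[nH]", "[N+]", "[O-]", "[n+]", "[NH+]",
    "[NH2+]", "[NH3+]", "[S+]", "[s+]", "[C@H]", "[C@@H]", "[C@]", "[C@@]",
    "[Si]", "[Se]", "[se]",
)

BLANK, GO, END = "_", "GO", "EOS"


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; concatenation reproduces the input."""
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"unknown SMILES character {smiles[pos]!r} at offset {pos}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass
class SmilesVocab:
    """Token index map with blank (0), GO and END control tokens."""

    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.tokens:
            self.tokens = [BLANK, GO, END, *DEFAULT_TOKENS]
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @classmethod
    def from_corpus(cls, smiles_iter) -> "SmilesVocab":
        seen = set()
        for s in smiles_iter:
            seen.update(tokenize(s))
        extra = sorted(seen - set(DEFAULT_TOKENS))
        return cls(tokens=[BLANK, GO, END, *DEFAULT_TOKENS, *extra])

    def __len__(self):
        return len(self.tokens)

    @property
    def blank(self) -> int:
        return self.index[BLANK]

    @property
    def go(self) -> int:
        return self.index[GO]

    @property
    def end(self) -> int:
        return self.index[END]

    def encode(self, smiles: str, max_len: int) -> np.ndarray:
        """GO + tokens + END, padded with the blank token to ``max_len``."""
        toks = tokenize(smiles)
        if len(toks) + 2 > max_len:
            raise ValueError(
                f"sequence of {len(toks)} tokens does not fit max_len={max_len}"
            )
        unknown = [t for t in toks if t not in self.index]
        if unknown:
            raise TokenizationError(f"tokens not in vocabulary: {unknown}")
        out = np.full(max_len, self.blank, dtype=np.int64)
        out[0] = self.go
        for i, t in enumerate(toks, start=1):
            out[i] = self.index[t]
        out[len(toks) + 1] = self.end
        return out

    def decode(self, indices) -> str:
        out = []
        for idx in np.asarray(indices, dtype=np.int64):
            if idx == self.end:
                break
            if idx in (self.blank, self.go):
                continue
            out.append(self.tokens[int(idx)])
        return "".join(out)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "SmilesVocab":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        return cls(tokens=tokens)


def encode_pair(
    scaffold: str, molecule: str, vocab: SmilesVocab, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Encode one scaffold/molecule SMILES pair to padded index vectors."""
    return vocab.encode(scaffold, max_len), vocab.encode(molecule, max_len)


def encode_pair_table(pairs, vocab: SmilesVocab, max_len: int):
    """Encode many pairs, dropping (and counting) over-length ones."""
    xs, ys, kept = [], [], []
    dropped = 0
    for p in pairs:
        try:
            x, y = encode_pair(p.scaffold, p.molecule_smiles, vocab, max_len)
        except ValueError:
            dropped += 1
            continue
        xs.append(x)
        ys.append(y)
        kept.append(p)
    if dropped:
        logger.info("encode_pair_table: dropped %d over-length pairs", dropped)
    if not xs:
        raise ValueError("no pairs fit the maximum sequence length")
    return np.stack(xs), np.stack(ys), kept
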