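"""Bag-of-words encoding: scaled expression rows become gene-token documents.

Each cell becomes one tagged document whose tokens are gene names repeated
as many times as the scaled (integer, 0-10) expression value — the direct
term-frequency analogy between a document/word corpus and an expression
matrix.  Token order within a cell is randomized (seeded, per-cell
independent streams) to remove positional bias; the multiset of tokens is
what carries information.
"""

from __future__ import annotations

import gzip
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def sanitize_gene_name(name: str) -> str:
    """Whitespace inside gene names would split one gene into several
    tokens; replace it so one gene is always exactly one token."""
    return "_".join(str(name).split())


@dataclass
class CellDocument:
    tag: str
    tokens: list[str]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    documents: list[CellDocument]
    vocabulary: set[str] = field(default_factory=set)
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        tags = [d.tag for d in self.documents]
        if len(set(tags)) != len(tags):
            raise ValueError("document tags must be unique")
        if not self.vocabulary:
            self.vocabulary = set()
            for d in self.documents:
                self.vocabulary.update(d.tokens)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def build_documents(E_scaled: ExpressionMatrix, seed: int, stream_by: str = "index") -> Corpus:
    """Encode a scaled matrix as one shuffled token document per cell.

    Gene g contributes exactly ``E'[g, c]`` copies of its (sanitized) name
    to cell c's document.  The shuffle for cell index i is driven by the
    independent stream ``(seed, i)``, so construction is order-independent
    and reproducible.  With ``stream_by="content"`` the per-cell stream is
    keyed by a hash of the cell's count profile instead of its index, so
    duplicated profiles yield byte-identical documents (used by the joint
    bulk + pseudo-bulk embedding).  All-zero cells yield empty documents,
    kept (with a warning) so cell indexing stays aligned with the matrix.
    """
    if E_scaled.layer != "scaled":
        raise ValueError("build_documents expects a scaled-layer matrix")
    if stream_by not in ("index", "content"):
        raise ValueError("stream_by must be 'index' or 'content'")
    names = np.array([sanitize_gene_name(g) for g in E_scaled.gene_ids])
    counts = E_scaled.values.astype(np.int64)
    docs: list[CellDocument] = []
    n_empty = 0
    for i, cell in enumerate(E_scaled.cell_ids):
        col = counts[:, i]
        toks = np.repeat(names, col)
        if toks.size == 0:
            n_empty += 1
        else:
            key = i if stream_by == "index" else zlib.crc32(col.tobytes()) & 0x7FFFFFFF
            rng = np.random.default_rng([seed, key])
            toks = rng.permutation(toks)
        docs.append(CellDocument(tag=cell, tokens=list(toks)))
    if n_empty:
        logger.warning("build_documents: %d cell(s) have all-zero scaled profiles "
                       "(empty documents retained)", n_empty)
    return Corpus(documents=docs, shuffle_seed=seed)


def corpus_stats(corpus: Corpus) -> dict:
    """Exact corpus summary: document, vocabulary and token counts."""
    lengths = np.array([len(d) for d in corpus.documents], dtype=int)
    return {
        "n_docs": len(corpus.documents),
        "vocab_size": len(corpus.vocabulary),
        "total_tokens": int(lengths.sum()) if lengths.size else 0,
        "tokens_per_doc": lengths,
    }


def counts_from_document(doc: CellDocument, gene_ids: list[str]) -> np.ndarray:
    """Rebuild an integer count vector over ``gene_ids`` from a document."""
    pos = {sanitize_gene_name(g): i for i, g in enumerate(gene_ids)}
    out = np.zeros(len(gene_ids), dtype=np.int64)
    for t in doc.tokens:
        out[pos[t]] += 1
    return out


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """One line per cell: ``tag<TAB>space-joined tokens`` (gzip by suffix)."""
    path = Path(path)
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for d in corpus.documents:
            fh.write(d.tag + "\t" + " ".join(d.tokens) + "\n")


def read_corpus(path: str | Path, shuffle_seed: int = 0) -> Corpus:
    path = Path(path)
    op = gzip.open if str(path).endswith(".gz") else open
    docs = []
    with op(path, "rt") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            tag, _, rest = ln.partition("\t")
            docs.append(CellDocument(tag=tag, tokens=rest.split() if rest else []))
    return Corpus(documents=docs, shuffle_seed=shuffle_seed)
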