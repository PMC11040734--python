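"""Branched peptide-dendrimer topology: sequence parsing, titratable sites,
and the branch-swap symmetry group.

Peptide dendrimers are tree-branched peptides built from branching lysines:
the side-chain amine of a branching lysine is amidated to carry a second
peptide arm, so each branching residue doubles the number of arms.  Sequences
are written in a one-letter notation as repeat blocks listed from the
periphery (G3) to the core (G0), e.g. ``(KL)_8(*K*KL)_4(*K*LL)_2*K*LLLL``:

* uppercase letters are L-amino acids, lowercase are D-amino acids;
* a letter wrapped in the branching sentinel (default ``*``) is a branching
  lysine (its side chain continues the tree and is therefore not titratable);
* a ``(C_16)`` suffix marks a palmitoylated (acylated) lysine whose side
  chain carries a lipid tail and never titrates;
* repeat counts must be consistent with a binary tree (8, 4, 2, then an
  unrepeated core block).

The parsed tree is rooted at the molecule's C-terminus (the C-terminal
residue of the core block): peptide dendrimers are synthesized C-to-N, so
every free amine — lysine side chains and the peripheral N-termini — points
away from the root.  C-termini are amide-capped and never titrate.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "TitratableSite",
    "DendrimerTopology",
    "SequenceParseError",
    "parse_dendrimer_sequence",
    "count_titratable_sites",
    "enumerate_branch_permutations",
]

LYS_SIDECHAIN = "LYS_SIDECHAIN"
N_TERMINUS = "N_TERMINUS"


class SequenceParseError(ValueError):
    """Raised when a dendrimer sequence string violates the block grammar."""


@dataclass
class Residue:
    """One residue (bead) of the dendrimer tree.

    ``children`` are ordered toward the periphery; at a branching lysine the
    first child arm continues through the alpha-amino group and the second
    through the side-chain amide (canonical ordering used for serialization
    and permutation indexing).
    """

    id: int
    code: str  # canonical one-letter code, uppercase
    chirality: str  # "L" | "D"
    generation: int
    role: str  # "linear" | "branching" | "acylated"
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    acyl: str | None = None  # e.g. "C16" for palmitoylated lysines


@dataclass(frozen=True)
class TitratableSite:
    """A proton-exchanging group: a free lysine side-chain amine or a free
    N-terminus at a peripheral branch end.  Both are cationic when
    protonated."""

    site_id: int
    residue_id: int
    kind: str  # LYS_SIDECHAIN | N_TERMINUS
    generation: int


@dataclass
class DendrimerTopology:
    name: str
    residues: list[Residue]
    sites: list[TitratableSite]
    branch_nodes: list[int]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def residue(self, rid: int) -> Residue:
        return self.residues[rid]

    @property
    def root(self) -> Residue:
        (root,) = [r for r in self.residues if r.parent is None]
        return root

    def generation_of(self, rid: int) -> int:
        return self.residues[rid].generation

    def residues_in_generation(self, generation: int) -> list[int]:
        return [r.id for r in self.residues if r.generation == generation]

    def sites_in_group(self, generation: int | None = None,
                       kind: str | None = None) -> list[TitratableSite]:
        """Sites filtered by generation and/or kind (None = no filter)."""
        out = []
        for s in self.sites:
            if generation is not None and s.generation != generation:
                continue
            if kind is not None and s.kind != kind:
                continue
            out.append(s)
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "residues": [
                {
                    "id": r.id,
                    "code": r.code,
                    "chirality": r.chirality,
                    "generation": r.generation,
                    "role": r.role,
                    "parent": r.parent,
                    "children": list(r.children),
                    "acyl": r.acyl,
                }
                for r in self.residues
            ],
            "sites": [
                {
                    "site_id": s.site_id,
                    "residue_id": s.residue_id,
                    "kind": s.kind,
                    "generation": s.generation,
                }
                for s in self.sites
            ],
            "branch_nodes": list(self.branch_nodes),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DendrimerTopology":
        residues = [Residue(**r) for r in d["residues"]]
        sites = [TitratableSite(**s) for s in d["sites"]]
        return cls(name=d["name"], residues=residues, sites=sites,
                   branch_nodes=list(d["branch_nodes"]))

    @classmethod
    def from_json(cls, text_or_path: str) -> "DendrimerTopology":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: residue token: optional branching sentinel around a letter, optional
#: acylation tag.  The acyl tag tolerates the underscore style of extracted
#: tables, e.g. "(C_16)" or "(C_16_)".
_TOKEN_RE_TEMPLATE = r"(?:{s}(?P<bletter>[A-Za-z]){s}|(?P<letter>[A-Za-z]))(?P<acyl>\(C_?\d+_?\))?"


@dataclass
class _Token:
    code: str
    chirality: str
    branching: bool
    acyl: str | None


def _tokenize_block(block: str, notation: str, sentinel: str) -> list[_Token]:
    tokens: list[_Token] = []
    pattern = re.compile(_TOKEN_RE_TEMPLATE.format(s=re.escape(sentinel)))
    pos = 0
    while pos < len(block):
        m = pattern.match(block, pos)
        if m is None:
            raise SequenceParseError(
                f"unrecognized text {block[pos:]!r} in block {block!r} "
                f"of {notation!r}")
        letter = m.group("bletter") or m.group("letter")
        code = letter.upper()
        if code not in _AA_LETTERS:
            raise SequenceParseError(
                f"unknown amino-acid letter {letter!r} in block {block!r}")
        branching = m.group("bletter") is not None
        if branching and code != "K":
            raise SequenceParseError(
                f"branching residue must be a lysine, got {letter!r} "
                f"in block {block!r}")
        acyl = None
        if m.group("acyl"):
            acyl = m.group("acyl").strip("()").replace("_", "")
            if code != "K":
                raise SequenceParseError(
                    f"acylation tag on non-lysine {letter!r} in block {block!r}")
        tokens.append(_Token(code=code,
                             chirality="L" if letter.isupper() else "D",
                             branching=branching, acyl=acyl))
        pos = m.end()
    if not tokens:
        raise SequenceParseError(f"empty block in {notation!r}")
    return tokens


def _split_blocks(notation: str) -> tuple[list[tuple[str, int]], str]:
    """Split a sequence into outer repeat blocks [(content, count), ...] and
    the trailing unrepeated core text.  Parentheses that are not followed by
    a repeat count (acyl tags) are left inside the block/core text."""
    s = notation.strip()
    blocks: list[tuple[str, int]] = []
    pos = 0
    repeat_re = re.compile(r"_(\d+)_?")
    while pos < len(s):
        if s[pos] != "(":
            break
        depth, j = 1, pos + 1
        while j < len(s) and depth:
            if s[j] == "(":
                depth += 1
            elif s[j] == ")":
                depth -= 1
            j += 1
        if depth:
            raise SequenceParseError(f"unbalanced parentheses in {notation!r}")
        m = repeat_re.match(s, j)
        if m is None:
            # a parenthesized group without a repeat count: part of the core
            break
        blocks.append((s[pos + 1:j - 1], int(m.group(1))))
        pos = m.end()
    core = s[pos:]
    if not core:
        raise SequenceParseError(
            f"missing unrepeated core block at the end of {notation!r}")
    return blocks, core


def parse_dendrimer_sequence(notation: str, name: str = "",
                             branch_sentinel: str = "*") -> DendrimerTopology:
    """Parse a branched one-letter dendrimer sequence into an explicit tree.

    Parameters
    ----------
    notation:
        Repeat-block sequence listed periphery-to-core, e.g.
        ``"(KL)_8(*K*KL)_4(*K*LL)_2*K*LLLL"``.
    name:
        Label stored on the topology (e.g. ``"MH18"``).
    branch_sentinel:
        Plain-text stand-in for the italic branching-lysine marker of the
        printed notation (default ``"*"``, i.e. ``*K*`` / ``*k*``).

    Returns
    -------
    DendrimerTopology
        With residues, generations, branch nodes and titratable sites fully
        populated.  Residue ids are assigned in a deterministic depth-first
        order from the C-terminal root.
    """
    blocks, core = _split_blocks(notation)
    block_tokens = [_tokenize_block(b, notation, branch_sentinel)
                    for b, _ in blocks]
    core_tokens = _tokenize_block(core, notation, branch_sentinel)

    counts = [c for _, c in blocks] + [1]  # outer ... core
    n_gen = len(counts)
    # binary-tree consistency: periphery-to-core counts must halve
    for i, (outer, inner) in enumerate(zip(counts, counts[1:])):
        if outer != 2 * inner:
            raise SequenceParseError(
                f"repeat count {outer} of block {blocks[i][0]!r} is not twice "
                f"the next inner count {inner}; counts inconsistent with "
                f"binary branching in {notation!r}")

    # generation of each block list entry: outermost = n_gen-1, core = 0
    all_tokens = block_tokens + [core_tokens]
    generations = list(range(n_gen - 1, -1, -1))

    for level, (tokens, gen) in enumerate(zip(all_tokens, generations)):
        n_branch = sum(t.branching for t in tokens)
        if level == 0:  # outermost (peripheral) block, or a plain peptide
            if n_branch != 0:
                raise SequenceParseError(
                    "outermost (peripheral) block may not contain a "
                    f"branching residue: {notation!r}")
        elif n_branch != 1:
            raise SequenceParseError(
                f"block at generation {gen} must contain exactly one "
                f"branching lysine, found {n_branch} in {notation!r}")
        if n_branch == 1 and not tokens[0].branching:
            raise SequenceParseError(
                "branching lysine must be the N-terminal residue of its "
                f"block in {notation!r}")

    residues: list[Residue] = []
    branch_nodes: list[int] = []

    def new_residue(tok: _Token, gen: int, parent: int | None) -> Residue:
        role = ("branching" if tok.branching
                else "acylated" if tok.acyl else "linear")
        r = Residue(id=len(residues), code=tok.code, chirality=tok.chirality,
                    generation=gen, role=role, parent=parent, acyl=tok.acyl)
        residues.append(r)
        if parent is not None:
            residues[parent].children.append(r.id)
        if tok.branching:
            branch_nodes.append(r.id)
        return r

    def build_block(level: int, parent: int | None) -> None:
        """Attach one block of generation ``generations[...]`` whose list
        index is ``level`` (0 = outermost).  Blocks attach via their
        C-terminal residue; the chain runs C→N toward the branching lysine,
        which then consumes two blocks of the next outer level."""
        tokens = all_tokens[level]
        gen = generations[level]
        branch: Residue | None = None
        # C-terminal token last in the block: walk reversed
        for tok in reversed(tokens):
            r = new_residue(tok, gen, parent)
            parent = r.id
            if tok.branching:
                branch = r
                break
        if branch is not None:
            if level == 0:
                raise SequenceParseError(
                    f"branching residue with no outer blocks in {notation!r}")
            build_block(level - 1, branch.id)  # alpha-amino arm
            build_block(level - 1, branch.id)  # side-chain arm

    build_block(n_gen - 1, None)

    # every block count must be consumed exactly: total residues check
    expected = sum(c * len(toks) for (_, c), toks in zip(blocks, block_tokens))
    expected += len(core_tokens)
    if len(residues) != expected:
        raise SequenceParseError(
            f"sequence {notation!r} builds {len(residues)} residues but the "
            f"repeat counts promise {expected}; counts inconsistent with "
            "binary branching")

    sites: list[TitratableSite] = []

    def add_site(residue: Residue, kind: str) -> None:
        sites.append(TitratableSite(site_id=len(sites),
                                    residue_id=residue.id, kind=kind,
                                    generation=residue.generation))

    for r in residues:
        if r.code == "K" and r.role == "linear":
            add_site(r, LYS_SIDECHAIN)
    for r in residues:
        if not r.children and r.role != "acylated":
            # peripheral branch terminus: free (titratable) N-terminus
            add_site(r, N_TERMINUS)

    return DendrimerTopology(name=name or notation, residues=residues,
                             sites=sites, branch_nodes=sorted(branch_nodes))


# ---------------------------------------------------------------------------
# site counting
# ---------------------------------------------------------------------------

def count_titratable_sites(topology: DendrimerTopology) -> dict[tuple[int, str], int]:
    """Count titratable sites partitioned by (generation, kind).

    The per-generation/per-kind partition is the grouping used when titration
    curves exploit the pseudo-symmetry of the tree (all sites of one kind in
    one generation are chemically equivalent).
    """
    counts: dict[tuple[int, str], int] = {}
    for s in topology.sites:
        key = (s.generation, s.kind)
        counts[key] = counts.get(key, 0) + 1
    assert sum(counts.values()) == topology.n_sites
    return counts


# ---------------------------------------------------------------------------
# branch-swap symmetry group
# ---------------------------------------------------------------------------

def _canonical_form(topology: DendrimerTopology, rid: int):
    r = topology.residue(rid)
    return (r.code, r.chirality, r.role, r.acyl,
            tuple(_canonical_form(topology, c) for c in r.children))


def _subtree_ids(topology: DendrimerTopology, rid: int) -> list[int]:
    out = [rid]
    for c in topology.residue(rid).children:
        out.extend(_subtree_ids(topology, c))
    return out


def _isomorphism(topology: DendrimerTopology, a: int, b: int) -> dict[int, int] | None:
    """Bijection a-subtree → b-subtree by parallel DFS, or None if the two
    subtrees differ in shape, codes, chirality, role or acylation."""
    ra, rb = topology.residue(a), topology.residue(b)
    if (ra.code, ra.chirality, ra.role, ra.acyl) != (rb.code, rb.chirality,
                                                     rb.role, rb.acyl):
        return None
    if len(ra.children) != len(rb.children):
        return None
    mapping = {a: b}
    for ca, cb in zip(ra.children, rb.children):
        sub = _isomorphism(topology, ca, cb)
        if sub is None:
            return None
        mapping.update(sub)
    return mapping


def swappable_branch_nodes(topology: DendrimerTopology) -> list[int]:
    """Branch nodes whose two child subtrees are topologically isomorphic
    (and whose arms may therefore be exchanged without changing the
    molecule).  Non-isomorphic nodes are skipped with a logged notice."""
    nodes = []
    for rid in topology.branch_nodes:
        c1, c2 = topology.residue(rid).children
        if _isomorphism(topology, c1, c2) is not None:
            nodes.append(rid)
        else:
            logger.info("branch node %d of %s has non-isomorphic arms; "
                        "excluded from the swap group", rid, topology.name)
    return nodes


def enumerate_branch_permutations(topology: DendrimerTopology) -> list[np.ndarray]:
    """Enumerate every composition of independent branch-arm swaps.

    Each branching lysine with two isomorphic arms may have its arms
    exchanged independently; a full third-generation dendrimer has 7 such
    nodes, giving ``2**7 = 128`` relabelings of the molecule onto itself.

    Returns
    -------
    list of ndarray
        Each a permutation ``perm`` of residue ids (``perm[old] = new``)
        mapping the dendrimer onto itself; the identity is included and the
        set is closed under composition.
    """
    n = topology.n_residues
    swap_nodes = swappable_branch_nodes(topology)

    swaps: list[np.ndarray] = []
    for rid in swap_nodes:
        c1, c2 = topology.residue(rid).children
        iso = _isomorphism(topology, c1, c2)
        assert iso is not None
        perm = np.arange(n)
        for a, b in iso.items():
            perm[a] = b
            perm[b] = a
        swaps.append(perm)

    perms: list[np.ndarray] = []
    identity = np.arange(n)
    for mask in itertools.product((False, True), repeat=len(swaps)):
        perm = identity
        for use, swap in zip(mask, swaps):
            if use:
                perm = swap[perm]
        perms.append(perm.copy())
    return perms
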