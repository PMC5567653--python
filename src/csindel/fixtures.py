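"""The bundled DGK-like synthetic family.

A 50-sequence family (10 isozymes x 5 vertebrate groups) evolved on a
fixed guide tree whose shape mirrors the published catalytic-domain
phylogeny: five deeply separated class clades, kappa and zeta each
split into two clusters, epsilon and theta on the longest stems, and a
very short edge joining classes I and IV (so its bootstrap support is
weak).  The planted indel inventory reproduces the signature catalogue
of the vertebrate DGK catalytic domain — a variable 16-24 aa class I
insert, a 2/4 aa paired-length class I/IV locus, a 1 aa deletion shared
by classes I+IV, 5 aa and 2 aa class I deletions, an 8 aa class III
deletion, 1-2 aa epsilon/theta events and a 3/4 aa paired epsilon/theta
locus — inside an alignment of exactly 364 columns of which 260 are
gap-free, the dimensions of the catalytic-domain segment the analysis
is defined on.  Twelve single-row decoy gap runs emulate the
non-signature alignment noise that accounts for the remaining gapped
columns.
"""

from __future__ import annotations

from .seqio import ISOZYMES, ISOZYME_TO_CLASS
from .simulate import (DecoySpec, DeleteSpec, InsertSpec, SimulationConfig,
                       SimulationResult, simulate_family)

GROUPS = ("mammal", "bird", "reptile", "amphibian", "fish")

CORE_LENGTH = 328
TOTAL_COLUMNS = 364
GAPFREE_COLUMNS = 260

#: catalytic-domain-like ATP motif planted at core columns 55-60
ATP_MOTIF_CORE_START = 55

#: expected scan output (by_class grouping) for the planted inventory
EXPECTED_CALLS = {
    "sig1":  ("group_specific", "insert_relative", {"I": (16, 24)}),
    "sig2":  ("paired_lengths", "insert_relative", {"I": (2, 2), "IV": (4, 4)}),
    "sig3":  ("group_specific", "deletion_relative", {"V": (2, 2)}),
    "sig4":  ("shared_by_groups", "deletion_relative", {"I": (1, 1), "IV": (1, 1)}),
    "sig5":  ("group_specific", "deletion_relative", {"V": (1, 1)}),
    "sig6a": ("group_specific", "deletion_relative", {"I": (5, 5)}),
    "sig6b": ("group_specific", "deletion_relative", {"I": (2, 2)}),
    "sig8":  ("group_specific", "deletion_relative", {"III": (8, 8)}),
    "sig9":  ("group_specific", "insert_relative", {"III": (2, 2)}),
    "sig10": ("paired_lengths", "deletion_relative", {"III": (3, 3), "V": (4, 4)}),
}


def _leaf(iso: str, grp: str) -> str:
    return f"{iso}_{grp}"


def _iso_subtree(iso: str) -> str:
    m, b, r, a, f = (_leaf(iso, g) for g in GROUPS)
    return (f"((({m}:0.05,{b}:0.05):0.04,({r}:0.05,{a}:0.06):0.04):0.04,"
            f"{f}:0.10)")


def _split_subtree(iso: str) -> tuple[str, str]:
    """Two clusters for an isozyme that branches polyphyletically."""
    m, b, r, a, f = (_leaf(iso, g) for g in GROUPS)
    cluster_a = f"({m}:0.06,{b}:0.06)"
    cluster_b = f"(({r}:0.06,{a}:0.07):0.04,{f}:0.10)"
    return cluster_a, cluster_b


def guide_tree_newick() -> str:
    """Fixed guide tree.

    Geometry notes: the invariant flank-mask columns dilute per-column
    divergence, so pairwise JTT distances read roughly half the nominal
    branch-length scale and deep paths compress further.  The marker
    edges are therefore kept well clear of the noise floor: long class
    stems (0.24) versus short backbone edges, 0.14 edges separating the
    two kappa and zeta clusters from their class-mates, a long (0.55)
    edge under the epsilon+theta pair so the tree midpoint falls on it
    for any plausible depth estimate, and a near-zero (0.01) edge
    joining classes I and IV so that association exists but with weak
    bootstrap support.
    """
    class1 = (f"({_iso_subtree('alpha')}:0.14,"
              f"({_iso_subtree('beta')}:0.10,{_iso_subtree('gamma')}:0.10):0.07)")
    ka, kb = _split_subtree("kappa")
    class2 = (f"({ka}:0.15,(({_iso_subtree('delta')}:0.08,"
              f"{_iso_subtree('eta')}:0.08):0.07,{kb}:0.07):0.14)")
    za, zb = _split_subtree("zeta")
    class4 = f"({za}:0.15,({_iso_subtree('iota')}:0.07,{zb}:0.07):0.14)"
    class3 = _iso_subtree("epsilon")
    class5 = _iso_subtree("theta")
    return (f"(({class3}:0.50,{class5}:0.45):0.55,{class2}:0.24,"
            f"({class1}:0.24,{class4}:0.24):0.005);")


def _clades() -> dict:
    by_class: dict[str, list] = {}
    for iso in ISOZYMES:
        cls = ISOZYME_TO_CLASS[iso]
        by_class.setdefault(cls, []).extend(_leaf(iso, g) for g in GROUPS)
    clades = {
        "classI": by_class["I"],
        "classII": by_class["II"],
        "classIII": by_class["III"],
        "classIV": by_class["IV"],
        "classV": by_class["V"],
        "classI_IV": by_class["I"] + by_class["IV"],
        "alpha_tetrapod": [_leaf("alpha", g)
                           for g in ("mammal", "bird", "reptile", "amphibian")],
        "gamma_mb": [_leaf("gamma", g) for g in ("mammal", "bird")],
    }
    return clades


def make_dgk_like_fixture(seed: int = 42) -> SimulationResult:
    """Simulate the bundled DGK-like family (byte-deterministic per seed)."""
    ms = ATP_MOTIF_CORE_START
    cfg = SimulationConfig(
        guide_tree=guide_tree_newick(),
        root_length=CORE_LENGTH,
        clades=_clades(),
        fixed_columns={ms: "G", ms + 1: "A", ms + 2: "G",
                       ms + 3: "T", ms + 4: "L", ms + 5: "G"},
        overrides=[(_leaf("kappa", "mammal"), ms + 5, "S")],
        inserts=[
            InsertSpec("sig9", 40, [("classIII", 2)]),
            InsertSpec("sig2", 235, [("classI_IV", 2), ("classIV", 2)]),
            InsertSpec("sig1", 290, [("classI", 16), ("alpha_tetrapod", 6),
                                     ("gamma_mb", 8)]),
        ],
        deletions=[
            DeleteSpec("sig10", 75, [("classIII", 3), ("classV", 4)]),
            DeleteSpec("sig6a", 110, [("classI", 5)]),
            DeleteSpec("sig6b", 135, [("classI", 2)]),
            DeleteSpec("sig8", 160, [("classIII", 8)]),
            DeleteSpec("sig4", 190, [("classI_IV", 1)]),
            DeleteSpec("sig5", 207, [("classV", 1)]),
            DeleteSpec("sig3", 255, [("classV", 2)]),
        ],
        decoys=[
            DecoySpec("alpha_mammal", 6, 3),
            DecoySpec("delta_bird", 12, 4),
            DecoySpec("zeta_reptile", 91, 3),
            DecoySpec("eta_fish", 96, 5),
            DecoySpec("beta_amphibian", 147, 4),
            DecoySpec("iota_mammal", 178, 3),
            DecoySpec("gamma_bird", 218, 4),
            DecoySpec("kappa_fish", 243, 4),
            DecoySpec("epsilon_reptile", 267, 3),
            DecoySpec("theta_mammal", 272, 5),
            DecoySpec("delta_fish", 305, 4),
            DecoySpec("eta_mammal", 312, 3),
        ],
        seed=int(seed),
        leaf_isozymes={_leaf(i, g): i for i in ISOZYMES for g in GROUPS},
        leaf_taxon_groups={_leaf(i, g): g for i in ISOZYMES for g in GROUPS},
    )
    result = simulate_family(cfg)
    aln = result.alignment
    assert aln.ncols == TOTAL_COLUMNS, aln.ncols
    arr = aln.array
    gapfree = int((~(arr == b"-").any(axis=0)).sum())
    assert gapfree == GAPFREE_COLUMNS, gapfree
    return result


def write_fixture(result: SimulationResult, outdir) -> dict:
    """Emit the fixture as text artifacts; returns the paths."""
    from pathlib import Path

    from .seqio import write_alignment, write_group_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "family.afa",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.tsv",
        "tree": outdir / "guide.nwk",
    }
    write_alignment(result.alignment, paths["alignment"])
    write_group_table(result.scheme, paths["groups"])
    result.truth.to_tsv(paths["truth"])
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(result.guide_tree.newick() + "\n")
    return paths
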