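"""Shipped molecular-topology fixtures for HA oligosaccharides.

Hyaluronan is the repeating disaccharide [GlcA-β(1→3)-GlcNAc-β(1→4)]ₙ.
Reductive amination with an aromatic amine (2AA = 2-aminobenzoic acid) opens
the reducing-terminal GlcNAc ring into an alditol chain whose C1 carries the
aniline nitrogen of the label.  The fixtures here provide:

* ``ha4_an`` / ``ha6_an``  — unmodified oligosaccharides, all rings closed
  and rigid (no sampled torsions);
* ``ha4_2aa`` / ``ha6_2aa`` — 2AA-modified oligosaccharides with rigid
  closed-ring anchors, a flexible opened GlcNAc chain (residue ``T``) and the
  2AA moiety (residue ``X``).

Geometry is idealized template geometry (canonical bond lengths/angles,
chair-like fixed ring dihedrals): rings are treated as rigid bodies and only
the listed rotatable bonds vary.  These are synthetic stand-ins for deposited
coordinates, which are not shipped; the glycosidic anchor values are
documented placeholders.  Torsion names for the opened terminus keep the
labels of the tetrasaccharide analysis ("T4 C2-C3", "T4 C1-C2",
"T4 C1-X5 NH11") in every fixture, because the same measured dynamic model
is transplanted onto longer oligosaccharides — only the atom quadruples
differ per topology.

Residue labels: HA₄-2AA = A1, S2, G3, T4, X5 (G = penultimate GlcA,
T = opened GlcNAc, X = 2AA); HA₆-2AA = A1, N2, A3, N4, G5, T6, X7.
"""

from __future__ import annotations

from hyalodyn.conformer_builder import Atom, MolecularTopology, Placement, TorsionRef
from hyalodyn.dynamics_model import (
    CodependentGroup,
    DynamicModel,
    TorsionMode,
    TorsionSpec,
)

__all__ = [
    "GROUP_ID",
    "TABLE3_GROUP",
    "dynamic_model_for",
    "get_topology",
    "ha4_2aa_topology",
    "ha4_an_topology",
    "ha6_2aa_topology",
    "ha6_an_topology",
]

# canonical template geometry (Å / degrees)
CC = 1.53
CO = 1.43
CN = 1.47
CAR = 1.39  # aromatic C-C
C_CARBOXYL = 1.52
CDO = 1.25  # carboxylate C-O
CH = 1.09
NH = 1.01
OH = 0.96
TET = 109.47
SP2 = 120.0

#: id of the codependent group of the opened terminus
GROUP_ID = "T4-X5"

#: Joint modes of the three codependent torsions of the opened GlcNAc /
#: aniline linkage: (C2-C3, C1-C2, C1-NH11) mode means with occupancies.
#: Libration widths: 20.0 about C2-C3, 4.7 about C1-C2, 4.4 about C1-NH11,
#: identical in every mode.
TABLE3_GROUP: list[tuple[tuple[float, float, float], float]] = [
    ((60.0, -60.0, -127.0), 0.35),
    ((180.0, -60.0, 116.9), 0.35),
    ((180.0, -60.0, -95.8), 0.22),
    ((-60.0, 180.0, -146.9), 0.06),
    ((-60.0, 180.0, 85.3), 0.02),
]
TABLE3_SIGMAS = (20.0, 4.7, 4.4)

#: unimodal torsions of the flexible terminus: name -> (mu, sigma).
#: The glycosidic anchor values and the hydroxyl/acetamido orientations are
#: placeholders (the source analysis defers them to prior work); C5-C6 uses
#: its reported dominant 180° state.
UNIMODAL_TERMINUS: dict[str, tuple[float, float]] = {
    "G-T phi": (-75.0, 10.0),
    "G-T psi": (120.0, 10.0),
    "T4 C3-C4": (180.0, 8.0),
    "T4 C4-C5": (-60.0, 8.0),
    "T4 C5-C6": (180.0, 8.0),
    "X5 N11-CA1": (180.0, 8.0),
}


class _Builder:
    """Accumulates atoms/bonds/placements with residue-qualified names."""

    def __init__(self, name: str):
        self.name = name
        self.atoms: list[Atom] = []
        self.bonds: list[tuple[str, str]] = []
        self.tree: list[Placement] = []
        self.anchor: list[str] = []
        self.jc: list[tuple[str, str, str, str]] = []
        self.stereo: list[tuple[str, tuple[str, str, str]]] = []

    def add(
        self,
        name: str,
        element: str,
        refs: tuple[str, ...],
        length: float = 0.0,
        angle: float = 0.0,
        dihedral: float | TorsionRef = 0.0,
        flags: frozenset[str] | set[str] = frozenset(),
        bond_to: str | None = "auto",
    ) -> str:
        residue = name.split(":", 1)[0]
        self.atoms.append(
            Atom(name=name, element=element, residue=residue, flags=frozenset(flags))
        )
        self.tree.append(
            Placement(atom=name, refs=refs, length=length, angle=angle, dihedral=dihedral)
        )
        if bond_to == "auto":
            bond_to = refs[0] if refs else None
        if bond_to is not None:
            self.bonds.append((bond_to, name))
        return name

    def build(self) -> MolecularTopology:
        return MolecularTopology(
            name=self.name,
            atoms=self.atoms,
            bonds=self.bonds,
            build_tree=self.tree,
            anchor_atoms=self.anchor,
            j_couplings=self.jc,
            stereocenters=self.stereo,
        )


def _add_ring(b: _Builder, res: str, incoming: tuple[str, str, str] | None) -> None:
    """Append one coarse rigid pyranose ring (C1..C5, O5 + anomeric O1).

    ``incoming`` is the (linker O, its C1, that C1's neighbour) triple of the
    previous residue, or None for the chain start.  Fixed ±55° dihedrals
    approximate a chair; the O5→C1 closing bond is recorded in ``bonds`` only.
    """
    if incoming is None:
        b.add(f"{res}:C4", "C", ())
        b.add(f"{res}:C3", "C", (f"{res}:C4",), CC)
        b.add(f"{res}:C2", "C", (f"{res}:C3", f"{res}:C4"), CC, TET)
    else:
        o_link, c_prev, ref_prev = incoming
        b.add(f"{res}:C4", "C", (o_link, c_prev, ref_prev), CO, 117.0, 120.0)
        b.add(f"{res}:C3", "C", (f"{res}:C4", o_link, c_prev), CC, TET, -130.0)
        b.add(f"{res}:C2", "C", (f"{res}:C3", f"{res}:C4", o_link), CC, TET, 170.0)
    b.add(f"{res}:C1", "C", (f"{res}:C2", f"{res}:C3", f"{res}:C4"), CC, TET, 55.0)
    b.add(f"{res}:O5", "O", (f"{res}:C1", f"{res}:C2", f"{res}:C3"), CO, TET, 55.0)
    b.add(
        f"{res}:C5", "C", (f"{res}:O5", f"{res}:C1", f"{res}:C2"), CO, 114.0, -55.0
    )
    b.bonds.append((f"{res}:C5", f"{res}:C4"))  # ring closure
    b.add(f"{res}:H1", "H", (f"{res}:C1", f"{res}:C2", f"{res}:C3"), CH, TET, -65.0)
    b.stereo.append((f"{res}:C1", (f"{res}:C2", f"{res}:O5", f"{res}:H1")))


def _add_link_oxygen(b: _Builder, res: str) -> str:
    """Anomeric oxygen O1 on C1, the attachment point of the next residue."""
    return b.add(
        f"{res}:O1", "O", (f"{res}:C1", f"{res}:C2", f"{res}:C3"), CO, TET, 175.0
    )


def _add_open_terminus(b: _Builder, g: str, t: str, x: str) -> None:
    """Flexible opened GlcNAc chain (residue ``t``) and 2AA moiety (``x``),
    attached to the last closed GlcA ring ``g`` via its anomeric carbon."""
    c1g, o5g, c5g = f"{g}:C1", f"{g}:O5", f"{g}:C5"
    T = TorsionRef

    o3 = b.add(f"{t}:O3", "O", (c1g, o5g, c5g), CO, 117.0, T("G-T phi"))
    c3 = b.add(f"{t}:C3", "C", (o3, c1g, o5g), CO, 117.0, T("G-T psi"))
    c4 = b.add(f"{t}:C4", "C", (c3, o3, c1g), CC, TET, -120.0)
    c2 = b.add(f"{t}:C2", "C", (c3, o3, c1g), CC, TET, 120.0)
    b.add(f"{t}:H3", "H", (c3, o3, c1g), CH, TET, 0.0)

    # rotation about C2-C3: canonical quadruple C4-C3-C2-C1
    c1 = b.add(f"{t}:C1", "C", (c2, c3, c4), CC, TET, T("T4 C2-C3"))
    n2 = b.add(
        f"{t}:N2", "N", (c2, c3, c4), CN, TET, T("T4 C2-C3", 120.0),
        flags={"hbond_donor"},
    )
    b.add(f"{t}:H2", "H", (c2, c3, c4), CH, TET, T("T4 C2-C3", -120.0))
    b.stereo.append((f"{t}:C2", (c1, c3, n2)))

    # acetamido group on N2
    b.add(f"{t}:HN2", "H", (n2, c2, c3), NH, SP2, 0.0)
    c7 = b.add(f"{t}:C7", "C", (n2, c2, c3), 1.33, SP2, 180.0)
    b.add(f"{t}:O7", "O", (c7, n2, c2), 1.23, SP2, 0.0, flags={"hbond_acceptor"})
    b.add(f"{t}:C8", "C", (c7, n2, c2), CC, SP2, 180.0, flags={"hydrophobic"})

    # rotation about C3-C4: quadruple C2-C3-C4-C5
    c5 = b.add(f"{t}:C5", "C", (c4, c3, c2), CC, TET, T("T4 C3-C4"))
    o4 = b.add(
        f"{t}:O4", "O", (c4, c3, c2), CO, TET, T("T4 C3-C4", 120.0),
        flags={"hbond_donor", "hbond_acceptor"},
    )
    b.add(f"{t}:H4", "H", (c4, c3, c2), CH, TET, T("T4 C3-C4", -120.0))
    b.add(f"{t}:HO4", "H", (o4, c4, c3), OH, TET, 180.0)
    b.stereo.append((f"{t}:C4", (c3, c5, o4)))

    # rotation about C4-C5: quadruple C3-C4-C5-C6
    c6 = b.add(f"{t}:C6", "C", (c5, c4, c3), CC, TET, T("T4 C4-C5"))
    o5 = b.add(
        f"{t}:O5", "O", (c5, c4, c3), CO, TET, T("T4 C4-C5", 120.0),
        flags={"hbond_donor", "hbond_acceptor"},
    )
    b.add(f"{t}:H5", "H", (c5, c4, c3), CH, TET, T("T4 C4-C5", -120.0))
    b.add(f"{t}:HO5", "H", (o5, c5, c4), OH, TET, 180.0)
    b.stereo.append((f"{t}:C5", (c4, c6, o5)))

    # rotation about C5-C6: quadruple C4-C5-C6-O6
    o6 = b.add(
        f"{t}:O6", "O", (c6, c5, c4), CO, TET, T("T4 C5-C6"),
        flags={"hbond_donor", "hbond_acceptor"},
    )
    b.add(f"{t}:H6A", "H", (c6, c5, c4), CH, TET, T("T4 C5-C6", 120.0))
    b.add(f"{t}:H6B", "H", (c6, c5, c4), CH, TET, T("T4 C5-C6", -120.0))
    b.add(f"{t}:HO6", "H", (o6, c6, c5), OH, TET, 180.0)

    # rotation about C1-C2: quadruple C3-C2-C1-N11
    n11 = b.add(
        f"{x}:N11", "N", (c1, c2, c3), CN, TET, T("T4 C1-C2"),
        flags={"hbond_donor"},
    )
    b.add(f"{x}:H1A", "H", (c1, c2, c3), CH, TET, T("T4 C1-C2", 120.0), bond_to=c1)
    b.add(f"{x}:H1B", "H", (c1, c2, c3), CH, TET, T("T4 C1-C2", -120.0), bond_to=c1)

    # rotation about C1-N11: quadruple C2-C1-N11-HN11 (paper-style label)
    hn11 = b.add(
        f"{x}:HN11", "H", (n11, c1, c2), NH, SP2, T("T4 C1-X5 NH11")
    )
    ca1 = b.add(
        f"{x}:CA1", "C", (n11, c1, c2), 1.40, SP2, T("T4 C1-X5 NH11", 180.0),
        flags={"aromatic", "hydrophobic"},
    )

    # 2AA aromatic ring; planarity via fixed dihedrals, CA5-CA6 closure bond
    ca2 = b.add(
        f"{x}:CA2", "C", (ca1, n11, c1), CAR, SP2, T("X5 N11-CA1"),
        flags={"aromatic", "hydrophobic"},
    )
    ca6 = b.add(
        f"{x}:CA6", "C", (ca1, n11, c1), CAR, SP2, T("X5 N11-CA1", 180.0),
        flags={"aromatic", "hydrophobic"},
    )
    ca3 = b.add(
        f"{x}:CA3", "C", (ca2, ca1, n11), CAR, SP2, 180.0,
        flags={"aromatic", "hydrophobic"},
    )
    ca4 = b.add(
        f"{x}:CA4", "C", (ca3, ca2, ca1), CAR, SP2, 0.0,
        flags={"aromatic", "hydrophobic"},
    )
    ca5 = b.add(
        f"{x}:CA5", "C", (ca4, ca3, ca2), CAR, SP2, 0.0,
        flags={"aromatic", "hydrophobic"},
    )
    b.bonds.append((ca5, ca6))
    b.add(f"{x}:HA3", "H", (ca3, ca2, ca1), CH, SP2, 180.0)
    b.add(f"{x}:HA4", "H", (ca4, ca3, ca2), CH, SP2, 180.0)
    b.add(f"{x}:HA5", "H", (ca5, ca4, ca3), CH, SP2, 180.0)
    b.add(f"{x}:HA6", "H", (ca6, ca1, n11), CH, SP2, 180.0)

    # ortho carboxylate (position 2 of the benzoic ring), coplanar with the
    # ring and oriented so O7A can accept the aniline N-H (the internal
    # hydrogen bond inferred from the small temperature coefficient)
    c7a = b.add(f"{x}:C7A", "C", (ca2, ca1, n11), C_CARBOXYL, SP2, 0.0)
    b.add(
        f"{x}:O7A", "O", (c7a, ca2, ca1), CDO, SP2, 0.0,
        flags={"carboxylate_O", "hbond_acceptor"},
    )
    b.add(
        f"{x}:O7B", "O", (c7a, ca2, ca1), CDO, SP2, 180.0,
        flags={"carboxylate_O", "hbond_acceptor"},
    )

    # vicinal proton pairs for 3J back-calculation
    b.jc.extend(
        [
            (f"{x}:H1A", c1, c2, f"{t}:H2"),
            (f"{x}:H1B", c1, c2, f"{t}:H2"),
            (f"{t}:H2", c2, c3, f"{t}:H3"),
            (f"{t}:H3", c3, c4, f"{t}:H4"),
            (f"{t}:H4", c4, c5, f"{t}:H5"),
            (hn11, n11, c1, f"{x}:H1A"),
            (hn11, n11, c1, f"{x}:H1B"),
        ]
    )


def _anchor_ring_chain(b: _Builder, labels: list[str]) -> tuple[str, str, str]:
    """Build a chain of coarse rigid rings; returns the (C1, O5, C5) of the
    final ring (the attachment frame for a flexible terminus)."""
    incoming = None
    for res in labels:
        _add_ring(b, res, incoming)
        if res != labels[-1]:
            o1 = _add_link_oxygen(b, res)
            incoming = (o1, f"{res}:C1", f"{res}:C2")
    for res in labels:
        for suffix in ("C1", "C2", "C3", "C4", "C5", "O5", "H1"):
            b.anchor.append(f"{res}:{suffix}")
        if res != labels[-1]:
            b.anchor.append(f"{res}:O1")
    last = labels[-1]
    return f"{last}:C1", f"{last}:O5", f"{last}:C5"


def ha4_2aa_topology() -> MolecularTopology:
    """HA₄-2AA: two closed rings + penultimate GlcA (A1, S2, G3, rigid) and
    the flexible opened GlcNAc (T4) with the 2AA label (X5)."""
    b = _Builder("ha4_2aa")
    _anchor_ring_chain(b, ["A1", "S2", "G3"])
    _add_open_terminus(b, "G3", "T4", "X5")
    return b.build()


def ha6_2aa_topology() -> MolecularTopology:
    """HA₆-2AA: five closed rings held rigid (the docking anchor) and the
    flexible opened GlcNAc (T6) with the 2AA label (X7)."""
    b = _Builder("ha6_2aa")
    _anchor_ring_chain(b, ["A1", "N2", "A3", "N4", "G5"])
    _add_open_terminus(b, "G5", "T6", "X7")
    return b.build()


def _closed_topology(name: str, labels: list[str]) -> MolecularTopology:
    b = _Builder(name)
    _anchor_ring_chain(b, labels)
    return b.build()


def ha4_an_topology() -> MolecularTopology:
    """Unmodified HA₄ (closed reducing-terminal GlcNAc), fully rigid."""
    return _closed_topology("ha4_an", ["A1", "N2", "A3", "N4"])


def ha6_an_topology() -> MolecularTopology:
    """Unmodified HA₆ (closed reducing-terminal GlcNAc), fully rigid."""
    return _closed_topology("ha6_an", ["A1", "N2", "A3", "N4", "A5", "N6"])


_TOPOLOGIES = {
    "ha4_2aa": ha4_2aa_topology,
    "ha6_2aa": ha6_2aa_topology,
    "ha4_an": ha4_an_topology,
    "ha6_an": ha6_an_topology,
}


def get_topology(name: str) -> MolecularTopology:
    """Look up a shipped topology fixture by preset name."""
    try:
        return _TOPOLOGIES[name]()
    except KeyError:
        raise KeyError(
            f"unknown topology preset {name!r}; available: {sorted(_TOPOLOGIES)}"
        ) from None


def dynamic_model_for(topology: MolecularTopology) -> DynamicModel:
    """The measured dynamic model of the 2AA-modified terminus, bound to the
    atom quadruples of ``topology``.

    The codependent group carries the five joint modes of the opened-ring
    backbone torsions with occupancies (0.35, 0.35, 0.22, 0.06, 0.02); the
    remaining terminus torsions are unimodal.  Raises for closed-ring
    topologies, which have no sampled torsions.
    """
    names = topology.torsion_names()
    if not names:
        raise ValueError(
            f"topology {topology.name!r} has no sampled torsions; "
            "closed-ring fixtures are rigid"
        )
    group_torsions = ["T4 C2-C3", "T4 C1-C2", "T4 C1-X5 NH11"]
    specs: dict[str, TorsionSpec] = {}
    for name in names:
        specs[name] = TorsionSpec(
            name=name,
            atoms=topology.torsion_quadruple(name),
            group_id=GROUP_ID if name in group_torsions else None,
        )
    modes = [
        {
            t: TorsionMode(mu=mus[k], sigma=TABLE3_SIGMAS[k])
            for k, t in enumerate(group_torsions)
        }
        for mus, _ in TABLE3_GROUP
    ]
    group = CodependentGroup(
        group_id=GROUP_ID,
        torsions=group_torsions,
        modes=modes,
        populations=[pi for _, pi in TABLE3_GROUP],
    )
    unimodal = {
        name: TorsionMode(mu=mu, sigma=sigma)
        for name, (mu, sigma) in UNIMODAL_TERMINUS.items()
        if name in names
    }
    return DynamicModel(
        specs=specs,
        unimodal=unimodal,
        groups=[group],
        metadata=f"2AA-terminus dynamic model bound to topology {topology.name}",
    )
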