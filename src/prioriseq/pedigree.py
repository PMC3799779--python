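"""Pedigree data model, PLINK PED ingestion, validation and kinship.

Pedigrees are modelled as rooted trees of nuclear-family units (a
couple plus its children).  Only loop-free pedigrees are supported:
every married-in spouse must be a founder and no consanguineous unions
are allowed — the inside-outside inference engine is exact only on
trees, so anything else aborts with a clear error rather than an
approximation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Individual",
    "NuclearUnit",
    "UnitTree",
    "Pedigree",
    "ObservedGenotypes",
    "parse_ped",
    "parse_ped_families",
    "write_ped",
    "kinship",
]

AFFECTED, UNAFFECTED, UNKNOWN = "affected", "unaffected", "unknown"
_PHENO_MAP = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


@dataclass
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affection: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class NuclearUnit:
    """A couple and its children; ``connector`` links it to the unit above."""

    father: str
    mother: str
    children: list[str]
    connector: str | None = None
    spouse: str | None = None


@dataclass
class UnitTree:
    """Rooted nuclear-unit decomposition, in deterministic pre-order."""

    units: list[NuclearUnit]
    order: list[int]  # pre-order over units
    root_individual: str


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    members: list[Individual]
    family_id: str = "FAM"

    def __post_init__(self) -> None:
        ids = [m.iid for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"duplicate individual ids in family {self.family_id}")
        self._index = {iid: k for k, iid in enumerate(ids)}
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(
                    f"{m.iid}: both parents must be present or both absent"
                )
            for pid in (m.father, m.mother):
                if pid is not None and pid not in self._index:
                    raise PedigreeError(f"{m.iid}: parent {pid} not in pedigree")

    @property
    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    @property
    def founders(self) -> list[str]:
        return [m.iid for m in self.members if m.is_founder]

    @property
    def n(self) -> int:
        return len(self.members)

    def index(self, iid: str) -> int:
        return self._index[iid]

    def member(self, iid: str) -> Individual:
        return self.members[self._index[iid]]

    def affected_count(self) -> int:
        return sum(m.affection == AFFECTED for m in self.members)

    # ------------------------------------------------------------------
    def nuclear_units(self) -> list[NuclearUnit]:
        """Group non-founders by their parental couple, in input order."""
        seen: dict[tuple[str, str], NuclearUnit] = {}
        for m in self.members:
            if m.is_founder:
                continue
            key = (m.father, m.mother)
            if key not in seen:
                seen[key] = NuclearUnit(father=m.father, mother=m.mother, children=[])
            seen[key].children.append(m.iid)
        return list(seen.values())

    def validate(self) -> UnitTree:
        """Check tree structure and return the rooted nuclear-unit tree.

        Verifies: single connected component; nobody is their own
        ancestor; parent sexes consistent with their roles; every
        married-in spouse is a founder and no union closes a loop.  The
        root is the first founder couple in input order.
        """
        self._check_parent_acyclic()
        self._check_sexes()
        self._check_connected()
        units = self.nuclear_units()
        if not units:
            if self.n != 1:
                raise PedigreeError("pedigree has multiple members but no parent links")
            return UnitTree(units=[], order=[], root_individual=self.members[0].iid)

        parent_units: dict[str, list[int]] = {}
        for k, u in enumerate(units):
            parent_units.setdefault(u.father, []).append(k)
            parent_units.setdefault(u.mother, []).append(k)

        root_idx = None
        for k, u in enumerate(units):
            if self.member(u.father).is_founder and self.member(u.mother).is_founder:
                root_idx = k
                break
        if root_idx is None:
            raise PedigreeError(
                "no founder couple found: pedigree contains a loop "
                "(married-in spouses must be founders)"
            )

        root = units[root_idx]
        root.connector, root.spouse = root.father, root.mother
        anchored = {root.father}
        order: list[int] = []
        seen = {root_idx}
        queue: deque[int] = deque([root_idx])
        while queue:
            ui = queue.popleft()
            u = units[ui]
            conn, spouse = u.connector, u.spouse
            if spouse in anchored:
                raise PedigreeError(
                    f"loop detected at union {u.father} x {u.mother}: "
                    f"{spouse} is already connected to the pedigree"
                )
            if ui != root_idx and not self.member(spouse).is_founder:
                raise PedigreeError(
                    f"loop detected at union {u.father} x {u.mother}: "
                    f"married-in spouse {spouse} is not a founder"
                )
            anchored.add(spouse)
            anchored.update(u.children)
            order.append(ui)
            for person in [conn, spouse] + u.children:
                for vi in parent_units.get(person, []):
                    if vi in seen:
                        continue
                    seen.add(vi)
                    v = units[vi]
                    v.connector = person
                    v.spouse = v.mother if v.father == person else v.father
                    queue.append(vi)
        if len(order) != len(units):
            raise PedigreeError("pedigree units do not form a single rooted tree")
        return UnitTree(units=units, order=order, root_individual=root.father)

    # ------------------------------------------------------------------
    def _check_parent_acyclic(self) -> None:
        state: dict[str, int] = {}  # 1 = on stack, 2 = done
        for start in self.ids:
            if start in state:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            state[start] = 1
            while stack:
                iid, pi = stack[-1]
                m = self.member(iid)
                parents = [p for p in (m.father, m.mother) if p is not None]
                if pi >= len(parents):
                    state[iid] = 2
                    stack.pop()
                    continue
                stack[-1] = (iid, pi + 1)
                pid = parents[pi]
                if state.get(pid) == 1:
                    raise PedigreeError(f"{pid} is its own ancestor")
                if pid not in state:
                    state[pid] = 1
                    stack.append((pid, 0))

    def _check_sexes(self) -> None:
        for m in self.members:
            if m.father is not None and self.member(m.father).sex == 2:
                raise PedigreeError(f"father {m.father} of {m.iid} is coded female")
            if m.mother is not None and self.member(m.mother).sex == 1:
                raise PedigreeError(f"mother {m.mother} of {m.iid} is coded male")

    def _check_connected(self) -> None:
        if self.n <= 1:
            return
        adj: dict[str, set[str]] = {m.iid: set() for m in self.members}
        for m in self.members:
            for pid in (m.father, m.mother):
                if pid is not None:
                    adj[m.iid].add(pid)
                    adj[pid].add(m.iid)
        start = self.members[0].iid
        seen = {start}
        queue = deque([start])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        if len(seen) != self.n:
            raise PedigreeError(
                f"family {self.family_id} has multiple connected components"
            )


@dataclass
class ObservedGenotypes:
    """Per-locus effect-allele dosages keyed by individual; NaN = missing."""

    locus_ids: list[str]
    dosages: dict[str, np.ndarray] = field(default_factory=dict)

    def matrix(self, ped: Pedigree) -> np.ndarray:
        """(members x loci) dosage matrix in pedigree member order."""
        L = len(self.locus_ids)
        out = np.full((ped.n, L), np.nan)
        for iid, row in self.dosages.items():
            if iid not in ped._index:
                raise PedigreeError(f"genotyped individual {iid} not in pedigree")
            out[ped.index(iid)] = row
        return out


# ----------------------------------------------------------------------
# PLINK PED text dialect


def _parse_rows(path: str | Path, panel) -> dict[str, tuple[list[Individual], dict]]:
    n_loci = panel.n_loci if panel is not None else 0
    fams: dict[str, tuple[list, dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise PedigreeError(
                    f"{path}:{lineno}: expected {6 + 2 * n_loci} fields, "
                    f"got {len(fields)}"
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            ind = Individual(
                iid=iid,
                father=None if pat == "0" else pat,
                mother=None if mat == "0" else mat,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
                affection=_PHENO_MAP.get(pheno, UNKNOWN),
            )
            dos = np.full(n_loci, np.nan)
            for i in range(n_loci):
                a1, a2 = fields[6 + 2 * i], fields[7 + 2 * i]
                if a1 == "0" or a2 == "0":
                    continue
                count = 0
                for a in (a1, a2):
                    if a == panel.effect_allele[i]:
                        count += 1
                    elif a != panel.other_allele[i]:
                        raise PedigreeError(
                            f"{path}:{lineno}: allele {a!r} at locus "
                            f"{panel.variant_id[i]} matches neither effect nor "
                            f"other allele"
                        )
                dos[i] = count
            members, gmap = fams.setdefault(fid, ([], {}))
            members.append(ind)
            gmap[iid] = dos
    return fams


def parse_ped_families(path: str | Path, panel=None) -> dict[str, tuple[Pedigree, ObservedGenotypes]]:
    """Parse a (possibly multi-family) PLINK PED file.

    ``panel`` supplies the locus definitions (effect/other alleles);
    dosages count copies of the effect allele, any missing allele in a
    pair marks the locus missing for that individual.  With
    ``panel=None`` the file must contain no genotype columns.
    """
    fams = _parse_rows(path, panel)
    loci = list(panel.variant_id) if panel is not None else []
    out = {}
    for fid, (members, gmap) in fams.items():
        ped = Pedigree(members=members, family_id=fid)
        obs = ObservedGenotypes(
            locus_ids=loci,
            dosages={i: d for i, d in gmap.items() if not np.all(np.isnan(d))},
        )
        out[fid] = (ped, obs)
    return out


def parse_ped(path: str | Path, panel=None) -> tuple[Pedigree, ObservedGenotypes]:
    """Parse a single-family PED file (error if several family ids)."""
    fams = parse_ped_families(path, panel)
    if len(fams) != 1:
        raise PedigreeError(
            f"{path}: expected one family, found {len(fams)} "
            f"({', '.join(sorted(fams))})"
        )
    return next(iter(fams.values()))


def write_ped(
    path: str | Path,
    ped: Pedigree,
    obs: ObservedGenotypes | None = None,
    panel=None,
) -> None:
    """Write a pedigree (and dosages, if given) back to PED text."""
    inv_pheno = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
    with open(path, "w") as fh:
        for m in ped.members:
            row = [
                ped.family_id,
                m.iid,
                m.father or "0",
                m.mother or "0",
                str(m.sex),
                inv_pheno[m.affection],
            ]
            if panel is not None and obs is not None:
                dos = obs.dosages.get(m.iid)
                for i in range(panel.n_loci):
                    d = np.nan if dos is None else dos[i]
                    if np.isnan(d):
                        row += ["0", "0"]
                    else:
                        ea, oa = panel.effect_allele[i], panel.other_allele[i]
                        d = int(d)
                        row += [ea] * d + [oa] * (2 - d)
            fh.write(" ".join(row) + "\n")


def kinship(ped: Pedigree) -> np.ndarray:
    """Kinship matrix by the standard recursion, members in pedigree order.

    phi(i,i) = 0.5 * (1 + phi(father_i, mother_i)); for j preceding i in
    a parents-first ordering, phi(i,j) = 0.5 * (phi(father_i, j) +
    phi(mother_i, j)) when i is a non-founder, else 0.
    """
    ped.validate()
    n = ped.n
    # topological order: parents before children
    order: list[int] = []
    placed: set[str] = set()
    pending = list(ped.members)
    while pending:
        rest = []
        for m in pending:
            if m.is_founder or (m.father in placed and m.mother in placed):
                order.append(ped.index(m.iid))
                placed.add(m.iid)
            else:
                rest.append(m)
        if len(rest) == len(pending):
            raise PedigreeError("cannot topologically order pedigree")
        pending = rest

    phi = np.zeros((n, n))
    pos = {k: r for r, k in enumerate(order)}
    for k in order:
        m = ped.members[k]
        if m.is_founder:
            phi[k, k] = 0.5
        else:
            fa, mo = ped.index(m.father), ped.index(m.mother)
            phi[k, k] = 0.5 * (1.0 + phi[fa, mo])
        for j in range(n):
            if j == k or pos[j] > pos[k]:
                continue
            val = 0.0
            if not m.is_founder:
                fa, mo = ped.index(m.father), ped.index(m.mother)
                val = 0.5 * (phi[fa, j] + phi[mo, j])
            phi[k, j] = phi[j, k] = val
    return phi
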