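"""Domain-insertion fusion: scan, splice, screen, and junction redesign shell.

The algorithm inserts one alpha/beta domain (the insert) into another (the
host) so that their beta sheets merge into a single extended sheet:

1. ``enumerate_probes`` — pair each of the first ``n_terminal_probe`` residues
   of the insert with each of the last ``n_terminal_probe`` (nine pairs at the
   default of three), the geometric search keys.
2. ``scan_insertion_sites`` — superpose each probe's backbone onto every host
   residue pair (i, j); a site is accepted when the pair RMSD is at most 1 Å
   and fewer than five host residues would be replaced.
3. ``splice_chimera`` — remove the host segment between i and j, graft the
   transformed insert, and connect the junctions with short linkers whose
   torsions are closed deterministically.
4. ``count_clashes`` / ``junction_is_continuous_strand`` — backbone-level
   steric screen and the requirement that the junction reads as one continuous
   beta strand.
5. ``select_redesign_shell`` / ``export_resfile`` — positions within 5 Å of
   the inter-domain junction interface, emitted as a Rosetta resfile for the
   downstream (out-of-package) sequence-design step.

Ranking uses (clash count, pair RMSD): a deterministic geometric proxy for
the energy- and packing-based selection a full design pipeline would apply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    RigidTransform,
    UnclosableGapError,
    close_gap,
    kabsch_superpose,
)
from .secstruct import assign_ss, junction_is_continuous_strand
from .structio import BackboneChain


@dataclass(frozen=True)
class FusionConfig:
    """Geometric thresholds of the insertion search.

    Defaults are the published protocol values: probes from three residues at
    each insert terminus, acceptance at 1 Å pair RMSD replacing host segments
    of fewer than 5 residues, 1-3 residue junction linkers, and a 5 Å
    redesign shell around the junction interface.  Clash thresholds are this
    package's backbone-level steric screen.
    """

    pair_rmsd_max: float = 1.0          # Å
    host_segment_max: int = 5           # replaced host residues, exclusive bound
    linker_lengths: tuple[int, ...] = (1, 2, 3)
    n_terminal_probe: int = 3
    clash_dist_ca: float = 3.2          # Å, CA-CA
    clash_dist_bb: float = 2.6          # Å, any other backbone atom pair
    clash_min_seq_sep: int = 3
    max_clashes: int = 0                # pipeline acceptance threshold
    shell_radius: float = 5.0           # Å

    def __post_init__(self) -> None:
        object.__setattr__(self, "linker_lengths",
                           tuple(sorted(set(int(x) for x in self.linker_lengths))))
        if not self.linker_lengths or any(x < 0 for x in self.linker_lengths):
            raise ValueError("linker_lengths must be non-empty, each >= 0")
        for name in ("pair_rmsd_max", "clash_dist_ca", "clash_dist_bb", "shell_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.host_segment_max < 1 or self.n_terminal_probe < 1:
            raise ValueError("host_segment_max and n_terminal_probe must be >= 1")

    @staticmethod
    def from_dict(d: dict) -> "FusionConfig":
        return FusionConfig(**{k: v for k, v in d.items()
                               if k in FusionConfig.__dataclass_fields__})


@dataclass(frozen=True)
class ResiduePairProbe:
    """One N-terminal and one C-terminal insert residue used as a search key."""
    n_index: int
    c_index: int
    atoms: np.ndarray  # (8, 3): N/CA/C/O of both residues

    def __post_init__(self) -> None:
        if self.n_index >= self.c_index:
            raise ValueError("probe n_index must precede c_index")


@dataclass(frozen=True)
class InsertionSite:
    probe: ResiduePairProbe
    host_i: int
    host_j: int
    pair_rmsd: float
    transform: RigidTransform           # insert frame -> host frame
    removed_segment: tuple[int, ...]    # host positions strictly between i and j


@dataclass
class ChimeraModel:
    """Spliced backbone with per-residue provenance (host/insert/linker).

    ``junction_groups`` holds the two boundaries separately (N-side and
    C-side); ``junction_residues`` is their flat union.
    """
    chain: BackboneChain
    provenance: list[str]
    junction_residues: tuple[int, ...]
    site: InsertionSite
    junction_groups: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.chain):
            raise ValueError("provenance must label every residue")


def enumerate_probes(insert: BackboneChain, config: FusionConfig | None = None
                     ) -> list[ResiduePairProbe]:
    """All (N-terminal residue, C-terminal residue) probe pairs of the insert,
    n_index-major order; n_terminal_probe² probes (nine at defaults)."""
    config = config or FusionConfig()
    k = config.n_terminal_probe
    n = len(insert)
    if n < 2 * k:
        raise ValueError(f"insert of {n} residues is too short for "
                         f"{k} probe residues per terminus")
    coords = insert.backbone_coords()
    probes = []
    for ni in range(k):
        for ci in range(n - k, n):
            probes.append(ResiduePairProbe(
                n_index=ni, c_index=ci,
                atoms=np.concatenate([coords[ni], coords[ci]])))
    return probes


def scan_insertion_sites(host: BackboneChain, insert: BackboneChain,
                         config: FusionConfig | None = None) -> list[InsertionSite]:
    """Align every probe against every host residue pair and keep matches.

    A host pair (i, j), i < j, is scanned when the replaced segment
    (j − i − 1 residues) is shorter than ``host_segment_max`` and no chain
    break interrupts host positions i..j.  The probe's two-residue backbone
    (8 atoms) is superposed onto the host pair's; the site is accepted when
    the RMSD is at most ``pair_rmsd_max``.  The probe's N-terminal residue
    always maps to host_i (forward orientation preserves chain direction).
    Results sorted by (pair_rmsd, host_i, host_j, probe order).
    """
    config = config or FusionConfig()
    probes = enumerate_probes(insert, config)
    coords = host.backbone_coords()
    n = len(host)
    sites: list[InsertionSite] = []
    for i in range(n):
        for j in range(i + 1, min(i + config.host_segment_max + 1, n)):
            if any(b in host.breaks for b in range(i, j)):
                continue
            target = np.concatenate([coords[i], coords[j]])
            for p_order, probe in enumerate(probes):
                res = kabsch_superpose(probe.atoms, target)
                if res.rmsd <= config.pair_rmsd_max:
                    sites.append(InsertionSite(
                        probe=probe, host_i=i, host_j=j,
                        pair_rmsd=res.rmsd, transform=res.transform,
                        removed_segment=tuple(range(i + 1, j))))
    sites.sort(key=lambda s: (s.pair_rmsd, s.host_i, s.host_j,
                              s.probe.n_index, s.probe.c_index))
    return sites


def expected_chimera_length(host_len: int, site: InsertionSite,
                            linker_len_n: int, linker_len_c: int) -> int:
    """Closed-form splice bookkeeping: host minus the removed segment, plus the
    insert span with its two probe residues merged into the retained host pair,
    plus the linkers."""
    removed = len(site.removed_segment)
    insert_span = site.probe.c_index - site.probe.n_index + 1
    return host_len - removed + (insert_span - 2) + linker_len_n + linker_len_c


def splice_chimera(host: BackboneChain, insert: BackboneChain, site: InsertionSite,
                   linker_len_n: int = 1, linker_len_c: int = 1) -> ChimeraModel:
    """Graft the transformed insert into the host at ``site``.

    The host residues at host_i/host_j are retained and the insert's probe
    residues are replaced by them (the superposition maps the insert onto the
    host frame, so the host pair keeps its sheet register).  Chain order:
    host[0..i] + N-linker + insert(n_index+1 .. c_index-1) + C-linker +
    host[j..].  Linkers start from extended torsions and are closed by
    deterministic coordinate descent on the terminal C-N distance; a gap a
    linker cannot span raises :class:`~sheetfuse.geometry.UnclosableGapError`.
    """
    host_coords = host.backbone_coords()
    ins_coords = site.transform.apply(
        insert.backbone_coords().reshape(-1, 3)).reshape(-1, 4, 3)

    p = site.probe
    mid = ins_coords[p.n_index + 1: p.c_index]          # insert minus probe residues
    pre = host_coords[: site.host_i + 1]
    post = host_coords[site.host_j:]

    def linker(anchor: np.ndarray, target_n: np.ndarray, length: int) -> np.ndarray:
        if length == 0:
            gap = float(np.linalg.norm(target_n - anchor[2]))
            if gap > 3.8:
                raise UnclosableGapError(
                    f"unclosable junction: direct bond gap {gap:.2f} Å")
            return np.zeros((0, 4, 3))
        return close_gap(anchor, target_n, length)

    link_n = linker(pre[-1], mid[0, 0], linker_len_n)
    link_c = linker(mid[-1] if len(mid) else pre[-1], post[0, 0], linker_len_c)

    coords = np.concatenate([pre, link_n, mid, link_c, post])
    provenance = (["host"] * len(pre) + ["linker"] * len(link_n)
                  + ["insert"] * len(mid) + ["linker"] * len(link_c)
                  + ["host"] * len(post))

    n_pre = len(pre)
    n_mid = len(mid)
    jn = [n_pre - 1] + list(range(n_pre, n_pre + linker_len_n)) + [n_pre + linker_len_n]
    c_first = n_pre + linker_len_n + n_mid - 1
    jc = [c_first] + list(range(c_first + 1, c_first + 1 + linker_len_c)) \
        + [c_first + 1 + linker_len_c]
    junction = tuple(sorted(set(jn + jc)))

    chain = BackboneChain.from_coords(
        coords,
        source_id=f"chimera:{host.source_id}+{insert.source_id}"
                  f"@{site.host_i}-{site.host_j}",
    )
    model = ChimeraModel(chain=chain, provenance=provenance,
                         junction_residues=junction, site=site,
                         junction_groups=(tuple(jn), tuple(jc)))
    assert len(chain) == expected_chimera_length(
        len(host), site, linker_len_n, linker_len_c)
    return model


def count_clashes(model: ChimeraModel | BackboneChain,
                  config: FusionConfig | None = None) -> int:
    """Residue pairs (sequence separation >= 3) with backbone atoms closer than
    the clash thresholds: 3.2 Å CA-CA or 2.6 Å for any other backbone pair."""
    config = config or FusionConfig()
    chain = model.chain if isinstance(model, ChimeraModel) else model
    coords = chain.backbone_coords()
    n = len(coords)
    flat = coords.reshape(-1, 3)
    res_of = np.repeat(np.arange(n), 4)
    atom_of = np.tile(np.arange(4), n)
    tree = cKDTree(flat)
    pairs = tree.query_pairs(max(config.clash_dist_ca, config.clash_dist_bb),
                             output_type="ndarray")
    clashing: set[tuple[int, int]] = set()
    for a, b in pairs:
        ri, rj = int(res_of[a]), int(res_of[b])
        if abs(ri - rj) < config.clash_min_seq_sep:
            continue
        d = float(np.linalg.norm(flat[a] - flat[b]))
        is_ca = atom_of[a] == 1 and atom_of[b] == 1
        lim = config.clash_dist_ca if is_ca else config.clash_dist_bb
        if d < lim:
            clashing.add((min(ri, rj), max(ri, rj)))
    return len(clashing)


def select_redesign_shell(model: ChimeraModel,
                          config: FusionConfig | None = None) -> set[int]:
    """Positions to redesign: everything within ``shell_radius`` (5 Å) of the
    inter-domain junction interface.

    The interface is (a) the junction residues themselves plus (b) every
    residue with a backbone atom within the shell radius of a backbone atom of
    a residue of different provenance (host vs insert contact).  The shell is
    all positions with any backbone atom within the radius of that interface;
    junction and linker residues are always included.
    """
    config = config or FusionConfig()
    coords = model.chain.backbone_coords()
    n = len(coords)
    flat = coords.reshape(-1, 3)
    res_of = np.repeat(np.arange(n), 4)
    tree = cKDTree(flat)
    pairs = tree.query_pairs(config.shell_radius, output_type="ndarray")

    prov = model.provenance
    interface: set[int] = set(model.junction_residues)
    contact_pairs = set()
    for a, b in pairs:
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri != rj and prov[ri] != prov[rj]:
            contact_pairs.add((ri, rj))
    for ri, rj in contact_pairs:
        interface.add(ri)
        interface.add(rj)

    shell: set[int] = set(interface)
    for a, b in pairs:
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri in interface:
            shell.add(rj)
        if rj in interface:
            shell.add(ri)
    shell |= {i for i, p in enumerate(prov) if p == "linker"}
    shell |= set(model.junction_residues)
    return shell


def export_resfile(shell: set[int], model: ChimeraModel) -> str:
    """Rosetta resfile marking the shell ALLAA over a NATRO default, using the
    model's emitted author numbering and chain id."""
    lines = ["NATRO", "start"]
    for pos in sorted(shell):
        res = model.chain.residues[pos]
        lines.append(f"{res.seq_id} {res.chain_id} ALLAA")
    return "\n".join(lines) + "\n"


def parse_resfile_positions(text: str, model: ChimeraModel) -> set[int]:
    """Inverse of :func:`export_resfile`: internal positions listed ALLAA."""
    by_author = {(r.chain_id, r.seq_id): i
                 for i, r in enumerate(model.chain.residues)}
    out = set()
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 3 and parts[2] == "ALLAA":
            out.add(by_author[(parts[1], int(parts[0]))])
    return out


@dataclass
class CandidateReport:
    """One scan/splice candidate and why it passed or failed."""
    probe_n: int
    probe_c: int
    host_i: int
    host_j: int
    pair_rmsd: float
    linker_n: int
    linker_c: int
    clashes: int | None = None
    junction_continuous: bool | None = None
    status: str = "pass"
    rank: int | None = None

    def row(self) -> list:
        return [self.probe_n, self.probe_c, self.host_i, self.host_j,
                round(self.pair_rmsd, 4), self.linker_n, self.linker_c,
                self.clashes, self.junction_continuous, self.status, self.rank]

    HEADER = ["probe_n", "probe_c", "host_i", "host_j", "pair_rmsd",
              "linker_n", "linker_c", "clashes", "junction_continuous",
              "status", "rank"]


def run_fusion_pipeline(host: BackboneChain, insert: BackboneChain,
                        config: FusionConfig | None = None
                        ) -> tuple[list[tuple[ChimeraModel, CandidateReport]],
                                   list[CandidateReport]]:
    """Full search: scan, splice over all allowed linker lengths, screen by
    clash count and junction strand continuity, rank by (clashes, pair RMSD).

    Returns (passing, report): ``passing`` is the ranked list of
    (ChimeraModel, its report row); ``report`` records every candidate with
    its pass/fail reason.  Fully deterministic given the inputs and config.
    """
    config = config or FusionConfig()
    sites = scan_insertion_sites(host, insert, config)
    report: list[CandidateReport] = []
    passing: list[tuple[ChimeraModel, CandidateReport]] = []

    for site in sites:
        for ln, lc in itertools.product(config.linker_lengths, repeat=2):
            cand = CandidateReport(
                probe_n=site.probe.n_index, probe_c=site.probe.c_index,
                host_i=site.host_i, host_j=site.host_j,
                pair_rmsd=site.pair_rmsd, linker_n=ln, linker_c=lc)
            try:
                model = splice_chimera(host, insert, site, ln, lc)
            except UnclosableGapError:
                cand.status = "fail:unclosable"
                report.append(cand)
                continue
            cand.clashes = count_clashes(model, config)
            try:
                ss = assign_ss(model.chain)
                # each boundary must read as one continuous strand, and both
                # must belong to the same merged sheet
                per_group = all(junction_is_continuous_strand(ss, g)
                                for g in model.junction_groups)
                one_sheet = any(set(model.junction_residues) <= sheet
                                for sheet in ss.sheets)
                cand.junction_continuous = per_group and one_sheet
            except ValueError:
                cand.junction_continuous = False
            if cand.clashes > config.max_clashes:
                cand.status = "fail:clashes"
            elif not cand.junction_continuous:
                cand.status = "fail:junction"
            else:
                cand.status = "pass"
                passing.append((model, cand))
            report.append(cand)

    passing.sort(key=lambda mc: (mc[1].clashes, mc[1].pair_rmsd,
                                 mc[1].host_i, mc[1].host_j,
                                 mc[1].probe_n, mc[1].probe_c,
                                 mc[1].linker_n, mc[1].linker_c))
    for rank, (_, cand) in enumerate(passing, start=1):
        cand.rank = rank
    return passing, report
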