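import numpy as np
import pytest

from sheetfuse import (
    FixtureSpec,
    FusionConfig,
    RigidTransform,
    UnclosableGapError,
    apply_transform,
    assign_ss,
    count_clashes,
    enumerate_probes,
    export_resfile,
    junction_is_continuous_strand,
    make_chimera_test_pair,
    make_fixture,
    run_fusion_pipeline,
    scan_insertion_sites,
    splice_chimera,
)
from sheetfuse.fusion import expected_chimera_length, parse_resfile_positions
from sheetfuse.structio import BackboneChain

from .oracles import brute_force_clashes, brute_force_sites


@pytest.fixture(scope="module")
def pair0():
    return make_chimera_test_pair(0)


class TestEnumerateProbes:
    def test_nine_probes_at_defaults(self, hairpin828):
        probes = enumerate_probes(hairpin828, FusionConfig())
        assert len(probes) == 9

    def test_order_is_deterministic_n_major(self, hairpin828):
        probes = enumerate_probes(hairpin828, FusionConfig())
        keys = [(p.n_index, p.c_index) for p in probes]
        n = len(hairpin828)
        assert keys == [(i, j) for i in range(3) for j in range(n - 3, n)]

    def test_single_probe_when_k_is_one(self, hairpin828):
        probes = enumerate_probes(hairpin828, FusionConfig(n_terminal_probe=1))
        assert [(p.n_index, p.c_index) for p in probes] == [(0, len(hairpin828) - 1)]

    def test_too_short_insert_errors(self):
        short = make_fixture(FixtureSpec("strand", (5,)))
        with pytest.raises(ValueError, match="too short"):
            enumerate_probes(short, FusionConfig())


class TestScan:
    def test_self_match_has_zero_rmsd_site(self, hairpin828):
        cfg = FusionConfig(host_segment_max=20)
        sites = scan_insertion_sites(hairpin828, hairpin828, cfg)
        assert sites and sites[0].pair_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_engineered_pair_single_site(self, pair0):
        host, insert, expected = pair0
        sites = scan_insertion_sites(host, insert, FusionConfig())
        assert len(sites) == 1
        s = sites[0]
        assert (s.probe.n_index, s.probe.c_index) == (
            expected.probe_n_index, expected.probe_c_index)
        assert (s.host_i, s.host_j) == (expected.host_i, expected.host_j)
        assert s.pair_rmsd < 0.1

    @pytest.mark.parametrize("seed,sigma", [(1, 0.0), (2, 0.25), (3, 0.25)])
    def test_matches_brute_force_oracle(self, seed, sigma):
        host, insert, _ = make_chimera_test_pair(seed, jitter_sigma=sigma)
        cfg = FusionConfig()
        got = {(s.probe.n_index, s.probe.c_index, s.host_i, s.host_j)
               for s in scan_insertion_sites(host, insert, cfg)}
        assert got == brute_force_sites(host, insert, cfg)

    def test_zero_threshold_yields_empty(self, pair0):
        host, insert, _ = pair0
        cfg = FusionConfig(pair_rmsd_max=0.0)
        assert scan_insertion_sites(host, insert, cfg) == []

    def test_sites_satisfy_acceptance_inequalities(self):
        host, insert, _ = make_chimera_test_pair(5, jitter_sigma=0.25)
        cfg = FusionConfig()
        for s in scan_insertion_sites(host, insert, cfg):
            assert s.pair_rmsd <= cfg.pair_rmsd_max
            assert len(s.removed_segment) < cfg.host_segment_max
            assert s.host_i < s.host_j

    def test_sorted_by_rmsd(self):
        host, insert, _ = make_chimera_test_pair(7, jitter_sigma=0.4)
        rmsds = [s.pair_rmsd for s in scan_insertion_sites(host, insert)]
        assert rmsds == sorted(rmsds)


class TestSplice:
    def test_bookkeeping_closed_form(self, engineered):
        host, insert = engineered["host"], engineered["insert"]
        cases = [(engineered["site"], 0, 0), (engineered["wide_site"], 0, 2),
                 (engineered["wide_site"], 0, 3)]
        for site, ln, lc in cases:
            model = splice_chimera(host, insert, site, ln, lc)
            assert len(model.chain) == expected_chimera_length(len(host), site, ln, lc)
            assert len(model.provenance) == len(model.chain)

    def test_peptide_bonds_in_range(self, engineered):
        host, insert = engineered["host"], engineered["insert"]
        for site, ln, lc in [(engineered["site"], 0, 0),
                             (engineered["wide_site"], 0, 2)]:
            model = splice_chimera(host, insert, site, ln, lc)
            bb = model.chain.backbone_coords()
            cn = np.linalg.norm(bb[1:, 0] - bb[:-1, 2], axis=1)
            assert cn.min() >= 1.2 and cn.max() <= 1.5
            assert not model.chain.breaks

    def test_provenance_boundaries(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["wide_site"], 0, 2)
        prov = model.provenance
        changes = sum(1 for a, b in zip(prov, prov[1:]) if a != b)
        assert changes == 3  # host->insert->linker->host (N-side bonds directly)
        assert prov[0] == prov[-1] == "host"
        assert prov.count("linker") == 2

    def test_squeezed_linker_is_unclosable(self, engineered):
        # the exact-overlap junction leaves a ~1.3 Å gap: no room for a residue
        with pytest.raises(UnclosableGapError):
            splice_chimera(engineered["host"], engineered["insert"],
                           engineered["site"], 1, 1)

    def test_unclosable_junction_raises(self, pair0):
        host, insert, _ = pair0
        from sheetfuse.fusion import InsertionSite, ResiduePairProbe
        probe = ResiduePairProbe(0, len(insert) - 1,
                                 np.concatenate([insert.backbone_coords()[0],
                                                 insert.backbone_coords()[-1]]))
        # a transform that throws the insert 100 Å away from the host
        far = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        site = InsertionSite(probe=probe, host_i=4, host_j=9, pair_rmsd=0.0,
                             transform=far, removed_segment=(5, 6, 7, 8))
        with pytest.raises(UnclosableGapError):
            splice_chimera(host, insert, site, 1, 1)

    def test_junction_reads_as_continuous_strand(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["site"], 0, 0)
        ss = assign_ss(model.chain)
        for pos in model.junction_residues:
            assert ss.states[pos] == "E"


class TestClashes:
    def test_clean_fixture_has_none(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["site"], 0, 0)
        assert count_clashes(model) == 0

    def test_superimposed_residues_clash(self, hairpin828):
        coords = hairpin828.backbone_coords().copy()
        coords[10] = coords[2]  # drop one residue onto another
        chain = BackboneChain.from_coords(coords)
        assert count_clashes(chain) >= 1

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            coords = rng.uniform(0, 18, size=(25, 1, 3)) + rng.normal(
                scale=0.8, size=(25, 4, 3))
            chain = BackboneChain.from_coords(coords)
            cfg = FusionConfig()
            assert count_clashes(chain, cfg) == brute_force_clashes(chain, cfg)


class TestRedesignShell:
    def test_linkers_and_junction_always_included(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["wide_site"], 0, 2)
        shell = select_redesign_shell_default(model)
        for i, p in enumerate(model.provenance):
            if p == "linker":
                assert i in shell
        assert set(model.junction_residues) <= shell

    def test_far_residues_excluded(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["site"], 0, 0)
        # graft a remote decoy residue >30 Å from everything at the C terminus
        coords = model.chain.backbone_coords()
        far = coords[-1:] + 50.0
        chain2 = BackboneChain.from_coords(np.concatenate([coords, far]))
        model2 = type(model)(chain=chain2,
                             provenance=model.provenance + ["host"],
                             junction_residues=model.junction_residues,
                             site=model.site)
        shell = select_redesign_shell_default(model2)
        assert len(chain2) - 1 not in shell

    def test_exhaustive_distance_enumeration(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["wide_site"], 0, 2)
        cfg = FusionConfig()
        shell = select_redesign_shell_default(model)
        coords = model.chain.backbone_coords()
        prov = model.provenance
        n = len(coords)

        def within(i, j, r):
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            return (d < r).any()

        interface = set(model.junction_residues)
        for i in range(n):
            for j in range(n):
                if i != j and prov[i] != prov[j] and within(i, j, cfg.shell_radius):
                    interface.update((i, j))
        expected = set(interface)
        for i in range(n):
            if any(within(i, j, cfg.shell_radius) for j in interface if j != i):
                expected.add(i)
        expected |= {i for i, p in enumerate(prov) if p == "linker"}
        assert shell == expected


def select_redesign_shell_default(model):
    from sheetfuse import select_redesign_shell
    return select_redesign_shell(model, FusionConfig())


class TestResfile:
    def test_dialect(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["site"], 0, 0)
        text = export_resfile({5, 6}, model)
        lines = text.splitlines()
        assert lines[0] == "NATRO" and lines[1] == "start"
        seq5 = model.chain.residues[5].seq_id
        seq6 = model.chain.residues[6].seq_id
        assert f"{seq5} A ALLAA" in lines and f"{seq6} A ALLAA" in lines

    def test_empty_shell_header_only(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["site"], 0, 0)
        assert export_resfile(set(), model).splitlines() == ["NATRO", "start"]

    def test_round_trip(self, engineered):
        model = splice_chimera(engineered["host"], engineered["insert"],
                               engineered["wide_site"], 0, 2)
        from sheetfuse import select_redesign_shell
        shell = select_redesign_shell(model, FusionConfig())
        assert parse_resfile_positions(export_resfile(shell, model), model) == shell


class TestPipeline:
    CFG = FusionConfig(linker_lengths=(0,), max_clashes=0)

    def test_engineered_pair_single_passing_chimera(self, pair0):
        host, insert, expected = pair0
        passing, report = run_fusion_pipeline(host, insert, self.CFG)
        assert len(passing) == 1
        model, cand = passing[0]
        assert cand.status == "pass" and cand.rank == 1
        assert (cand.probe_n, cand.probe_c) == (
            expected.probe_n_index, expected.probe_c_index)
        ss = assign_ss(model.chain)
        assert junction_is_continuous_strand(ss, model.junction_residues[:2])

    def test_zero_threshold_all_rejected_at_scan(self, pair0):
        host, insert, _ = pair0
        passing, report = run_fusion_pipeline(
            host, insert, FusionConfig(pair_rmsd_max=0.0))
        assert passing == [] and report == []

    def test_linker_order_irrelevant(self, pair0):
        host, insert, _ = pair0
        cfg_a = FusionConfig(linker_lengths=(0, 1, 2))
        cfg_b = FusionConfig(linker_lengths=(2, 0, 1))
        pa, ra = run_fusion_pipeline(host, insert, cfg_a)
        pb, rb = run_fusion_pipeline(host, insert, cfg_b)
        assert [c.row() for _, c in pa] == [c.row() for _, c in pb]
        assert [c.row() for c in ra] == [c.row() for c in rb]

    def test_rigid_invariance_of_decisions(self, pair0, rng):
        host, insert, _ = pair0
        base_pass, base_rep = run_fusion_pipeline(host, insert, self.CFG)
        base_rows = [c.row() for c in base_rep]
        for _ in range(3):
            th = RigidTransform.random(rng)
            ti = RigidTransform.random(rng)
            p2, r2 = run_fusion_pipeline(apply_transform(host, th),
                                         apply_transform(insert, ti), self.CFG)
            assert [c.row() for c in r2] == base_rows
            assert len(p2) == len(base_pass)
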