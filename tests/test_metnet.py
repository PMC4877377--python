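"""Metabolic-network frontend: I/O, flux geometry, EMs, knockouts, CLI."""

import json
from fractions import Fraction

import pytest
from click.testing import CliRunner

from confelem import cli, fixtures
from confelem.decompose import verify
from confelem.enumeration import evs_polyhedron
from confelem.exactla import vec
from confelem.geometry import conforms
from confelem.metnet import (
    MetabolicNetwork,
    decompose_flux,
    elementary_modes,
    flux_cone,
    flux_polyhedron,
    knockout_filter,
    read_flux,
    read_network,
    write_evset,
)

MODEL_TSV = (
    "\tR1\tR2\tR3\tR4\n"
    "X1\t1\t-1\t0\t-1\n"
    "X2\t0\t1\t-1\t0\n"
)


@pytest.fixture
def model_files(tmp_path):
    model = tmp_path / "model.tsv"
    model.write_text(MODEL_TSV)
    cons = tmp_path / "constraints.json"
    cons.write_text(json.dumps({"irreversible": [1, 2, 3]}))
    return model, cons


@pytest.fixture
def bounded_files(tmp_path):
    model = tmp_path / "model.tsv"
    model.write_text(MODEL_TSV)
    cons = tmp_path / "constraints.json"
    cons.write_text(
        json.dumps({"irreversible": ["R1", "R2", "R3"], "bounds": {"R1": [None, 2]}})
    )
    return model, cons


class TestReadNetwork:
    def test_running_example(self, model_files):
        net = read_network(*model_files)
        assert net.n_metabolites == 2 and net.n_reactions == 4
        assert net.irreversible == {0, 1, 2}
        assert net.N.row(0) == vec((1, -1, 0, -1))

    def test_bounds_and_name_resolution(self, bounded_files):
        net = read_network(*bounded_files)
        assert net.bounds == {0: (None, Fraction(2))}
        assert net.reaction_index("R4") == 3
        assert net.reaction_index(4) == 3
        assert net.reaction_index("4") == 3

    def test_null_bounds_mean_unbounded(self, tmp_path, model_files):
        model, _ = model_files
        cons = tmp_path / "c2.json"
        cons.write_text(json.dumps({"irreversible": [1], "bounds": {"4": [None, None]}}))
        net = read_network(model, cons)
        assert net.bounds == {3: (None, None)}
        assert not net.has_finite_bounds

    def test_bad_bounds_rejected(self, tmp_path, model_files):
        model, _ = model_files
        cons = tmp_path / "bad.json"
        cons.write_text(json.dumps({"bounds": {"R1": [3, 1]}}))
        with pytest.raises(ValueError, match="lower bound exceeds"):
            read_network(model, cons)

    def test_unknown_reaction_rejected(self, tmp_path, model_files):
        model, _ = model_files
        cons = tmp_path / "bad.json"
        cons.write_text(json.dumps({"irreversible": ["R9"]}))
        with pytest.raises((KeyError, IndexError)):
            read_network(model, cons)

    def test_float_entries_rejected(self, tmp_path):
        model = tmp_path / "model.tsv"
        model.write_text("\tR1\tR2\nX1\t0.5\t1\n")
        with pytest.raises((TypeError, ValueError)):
            read_network(model)

    def test_duplicate_reaction_ids_rejected(self, tmp_path):
        model = tmp_path / "model.tsv"
        model.write_text("\tR1\tR1\nX1\t1\t-1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_network(model)


class TestFluxGeometry:
    def test_flux_cone(self, running_network):
        C = flux_cone(running_network)
        assert C.contains(vec((2, 1, 1, 1)))
        assert C.nonneg == {0, 1, 2}

    def test_no_irreversible_gives_plain_subspace(self, running_network):
        net = MetabolicNetwork(
            running_network.metabolites,
            running_network.reactions,
            running_network.N,
            frozenset(),
        )
        C = flux_cone(net)
        assert C.contains(vec((-1, 0, 0, -1)))

    def test_flux_polyhedron_membership_with_bound(self):
        net = fixtures.running_example_network(bound_f1=2)
        P = flux_polyhedron(net)
        assert P.contains(vec((2, 1, 1, 1)))
        assert not P.contains(vec((3, 3, 3, 0)))

    def test_flux_polyhedron_requires_finite_bound(self, running_network):
        with pytest.raises(ValueError, match="no finite bounds"):
            flux_polyhedron(running_network)


class TestElementaryModes:
    def test_running_example(self, running_network):
        assert elementary_modes(running_network).rays == {
            (1, 0, 0, 1),
            (0, 1, 1, -1),
            (1, 1, 1, 0),
        }

    def test_single_pathway(self):
        net = MetabolicNetwork(
            ("X1",),
            ("R1", "R2"),
            fixtures.RationalMatrix([[1, -1]]),
            frozenset({0, 1}),
        )
        assert elementary_modes(net).rays == {(1, 1)}

    def test_full_column_rank_gives_no_modes(self):
        net = MetabolicNetwork(
            ("X1", "X2"),
            ("R1", "R2"),
            fixtures.RationalMatrix([[1, 0], [0, 1]]),
            frozenset({0}),
        )
        assert len(elementary_modes(net)) == 0

    def test_invariant_under_column_reordering(self, running_network):
        perm = [3, 0, 2, 1]
        N = running_network.N
        permuted = MetabolicNetwork(
            running_network.metabolites,
            tuple(running_network.reactions[p] for p in perm),
            fixtures.RationalMatrix(
                [[N.row(j)[p] for p in perm] for j in range(2)]
            ),
            frozenset(perm.index(i) for i in running_network.irreversible),
        )
        original = elementary_modes(running_network).rays
        relabeled = {
            tuple(r[perm.index(i)] for i in range(4))
            for r in elementary_modes(permuted).rays
        }
        assert relabeled == original


class TestDecomposeFlux:
    def test_cancelation_free(self, running_network):
        s = decompose_flux(running_network, vec((2, 1, 1, 1)))
        assert {tuple(int(v) for v in t) for t in s.cone_terms} == {
            (1, 0, 0, 1),
            (1, 1, 1, 0),
        }
        assert verify(s, flux_cone(running_network))

    def test_reversible_class(self, running_network):
        s = decompose_flux(running_network, vec((0, 2, 2, -2)))
        assert s.cone_terms == (vec((0, 2, 2, -2)),)

    def test_zero_flux(self, running_network):
        s = decompose_flux(running_network, vec((0, 0, 0, 0)))
        assert s.n_terms == 0

    def test_no_reaction_runs_both_directions(self, running_network):
        """No coordinate carries opposite signs across contributing terms."""
        for f in [(2, 1, 1, 1), (0, 2, 2, -2), (3, 1, 1, 2)]:
            s = decompose_flux(running_network, vec(f))
            for i in range(4):
                signs = {(t[i] > 0) - (t[i] < 0) for t in s.cone_terms} - {0}
                assert len(signs) <= 1
            for t in s.cone_terms:
                assert conforms(t, vec(f))

    def test_bounded_route(self):
        net = fixtures.running_example_network(bound_f1=2)
        s = decompose_flux(net, vec((2, 1, 1, 1)))
        assert s.convex_terms and s.weight_total == 1

    def test_infeasible_flux_rejected(self, running_network):
        with pytest.raises(ValueError):
            decompose_flux(running_network, vec((0, 1, 1, 1)))


class TestKnockout:
    def test_flux_polyhedron_knockout(self):
        net = fixtures.running_example_network(bound_f1=2)
        evs = evs_polyhedron(flux_polyhedron(net))
        filtered = knockout_filter(evs, 3)
        assert filtered.rays == frozenset()
        assert filtered.points == {vec((2, 2, 2, 0)), vec((0, 0, 0, 0))}

    def test_filter_equals_recomputation(self):
        """Filtering EVs by f4 = 0 equals re-enumerating with f4 = 0 appended."""
        net = fixtures.running_example_network(bound_f1=2)
        filtered = knockout_filter(evs_polyhedron(flux_polyhedron(net)), 3)
        knocked = fixtures.running_example_network(bound_f1=2, knockout_f4=True)
        recomputed = evs_polyhedron(flux_polyhedron(knocked))
        assert filtered.rays == recomputed.rays
        assert filtered.points == recomputed.points

    def test_cone_knockout(self, running_network):
        filtered = knockout_filter(elementary_modes(running_network), 3)
        assert filtered.rays == {(1, 1, 1, 0)}

    def test_knockout_can_empty_the_set(self, running_network):
        ems = elementary_modes(running_network)
        step = knockout_filter(knockout_filter(ems, 3), 1)
        assert len(step) == 0

    def test_index_guard(self, running_network):
        with pytest.raises(IndexError):
            knockout_filter(elementary_modes(running_network), 4)


class TestRoundTripsAndCLI:
    def test_evset_tsv_roundtrip(self, tmp_path, running_network):
        evs = elementary_modes(running_network)
        out = tmp_path / "ems.tsv"
        write_evset(evs, out, names=running_network.reactions)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "kind\tR1\tR2\tR3\tR4"
        assert len(lines) == 4

    def test_read_flux_tsv_and_json(self, tmp_path, model_files, running_network):
        tsv = tmp_path / "f.tsv"
        tsv.write_text("R1\t2\nR2\t1\nR3\t1\nR4\t1\n")
        assert read_flux(tsv, running_network) == vec((2, 1, 1, 1))
        js = tmp_path / "f.json"
        js.write_text(json.dumps({"R1": 2, "R2": 1, "R3": 1, "R4": 1}))
        assert read_flux(js, running_network) == vec((2, 1, 1, 1))
        bad = tmp_path / "missing.tsv"
        bad.write_text("R1\t2\n")
        with pytest.raises(ValueError, match="missing"):
            read_flux(bad, running_network)

    def test_cli_ems_and_decompose(self, tmp_path, model_files):
        model, cons = model_files
        runner = CliRunner()
        out = tmp_path / "ems.tsv"
        result = runner.invoke(
            cli.main, ["ems", "--model", str(model), "--constraints", str(cons),
                       "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert len(out.read_text().strip().splitlines()) == 4

        flux = tmp_path / "f.tsv"
        flux.write_text("R1\t2\nR2\t1\nR3\t1\nR4\t1\n")
        sum_out = tmp_path / "sum.json"
        result = runner.invoke(
            cli.main, ["decompose", "--model", str(model), "--constraints",
                       str(cons), "--flux", str(flux), "--out", str(sum_out)]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(sum_out.read_text())
        assert payload["certificate"]["ok"] is True
        assert len(payload["cone_terms"]) == 2

    def test_cli_knockout_and_selftest(self, tmp_path, bounded_files):
        model, cons = bounded_files
        runner = CliRunner()
        out = tmp_path / "ko.tsv"
        result = runner.invoke(
            cli.main, ["knockout", "--model", str(model), "--constraints",
                       str(cons), "--reaction", "R4", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 3  # header + two surviving points

        result = runner.invoke(cli.main, ["selftest"])
        assert result.exit_code == 0, result.output
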