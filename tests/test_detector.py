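"""Two-step β-layer detection: windows, pairing, annotation."""

import itertools

import numpy as np
import pytest

from betalayer.chain import StructureModel
from betalayer.detector import (
    annotate_layer_registers,
    annotate_transition,
    classify_capping,
    detect_beta_layers,
    layers_to_table,
    pair_strands,
    scan_windows,
)
from betalayer.geometry import compute_torsions
from betalayer.synthetic import (
    CrickParams,
    build_backbone_from_torsions,
    generate_beta_layer_fixture,
    generate_crick_coil,
)
from tests.conftest import random_rigid_transform

ALPHA = (-57.8, -47.0)
BETA = (-110.0, 140.0)


def chain_from_classes(classes: str, chain_id="A", sequence=None):
    """Build a chain whose torsion classes spell the given a/b string.

    The first and last residues of a chain have undefined classes, so the
    pattern is padded with one extra residue on each side.
    """
    tors = [ALPHA] + [ALPHA if c == "a" else BETA for c in classes] + [ALPHA]
    seq = None if sequence is None else "A" + sequence + "A"
    return build_backbone_from_torsions(tors, chain_id=chain_id, sequence=seq)


def candidates_for(classes: str, sequence=None):
    chain = chain_from_classes(classes, sequence=sequence)
    ts = compute_torsions(chain)
    return scan_windows({"A": ts}, {"A": chain}), chain


def brute_force_windows(classes: str):
    """Independent enumeration of the expected candidate triplets."""
    padded = "u" + classes + "u"
    hits = set()
    for i in range(len(padded) - 6):
        w = padded[i : i + 7]
        if w == "bbbaaaa":
            hits.add(i)
        if w == "aaaabbb":
            hits.add(i + 4)
    return sorted(hits)


class TestScanWindows:
    @pytest.mark.parametrize(
        "classes",
        [
            "aaaabbbaaaa",   # matched by both patterns
            "aaabbbaaaa",    # only 3 upstream alpha: bbbaaaa only
            "aaaabbb",       # no downstream flank at all
            "bbbaaaa",
            "aaaaaaa",       # all alpha: nothing
            "aaaabbbbaaaa",  # four beta in a row: no clean triplet window
            "aaaabbbaaaabbbaaaa",  # two layers
        ],
    )
    def test_matches_brute_force_enumeration(self, classes):
        cands, _ = candidates_for(classes)
        assert [c.indices[0] for c in cands] == brute_force_windows(classes)

    def test_double_match_merges_with_both_patterns(self):
        cands, _ = candidates_for("aaaabbbaaaa")
        assert len(cands) == 1
        assert cands[0].patterns == frozenset({"bbbaaaa", "aaaabbb"})
        # central residue is the middle beta
        assert cands[0].central_index == cands[0].indices[1]

    def test_single_sided_match_records_one_pattern(self):
        cands, _ = candidates_for("aaabbbaaaa")
        assert len(cands) == 1
        assert cands[0].patterns == frozenset({"bbbaaaa"})

    def test_empty_input(self):
        assert scan_windows({}, {}) == []


class TestPairStrands:
    def test_c3_fixture_forms_one_canonical_layer(self, nonad_fixture):
        model, ann = nonad_fixture
        torsions = {c.chain_id: compute_torsions(c) for c in model.chains}
        chains = {c.chain_id: c for c in model.chains}
        cands = scan_windows(torsions, chains)
        assert len(cands) == 3
        layers = pair_strands(cands, model)
        assert len(layers) == 1
        assert layers[0].n_strands == 3 and layers[0].canonical
        got = {(s.chain_id, s.seq_ids) for s in layers[0].strands}
        want = {
            (cid, ann.planted_layers[0].strand_seq_ids)
            for cid in ann.planted_layers[0].chain_ids
        }
        assert got == want

    def test_isolated_strand_forms_no_layer(self):
        chain = chain_from_classes("aaaabbbaaaa")
        model = StructureModel("iso", [chain])
        ts = {"A": compute_torsions(chain)}
        cands = scan_windows(ts, {"A": chain})
        assert len(cands) == 1
        assert pair_strands(cands, model) == []

    def test_same_chain_strands_may_pair(self, nonad_fixture):
        """Pseudo-threefold monomer: all strands renamed into one chain."""
        model, _ = nonad_fixture
        merged_ids, merged_icodes, merged_aas = [], [], []
        coords = {n: [] for n in ("N", "CA", "C", "O")}
        offset = 0
        for c in model.chains:
            merged_ids += [s + offset for s in c.seq_ids]
            merged_icodes += c.icodes
            merged_aas += c.aas
            for n in coords:
                coords[n].append(c.coords[n])
            offset += 1000
        from betalayer.chain import BackboneChain

        merged = BackboneChain(
            "A", merged_ids, merged_icodes, merged_aas,
            {n: np.vstack(v) for n, v in coords.items()},
        )
        mono = StructureModel("mono", [merged])
        layers = detect_beta_layers(mono)
        assert len(layers) == 1
        assert layers[0].n_strands == 3
        assert {s.chain_id for s in layers[0].strands} == {"A"}

    def test_cutoff_monotonicity(self, nonad_fixture):
        model, _ = nonad_fixture
        torsions = {c.chain_id: compute_torsions(c) for c in model.chains}
        chains = {c.chain_id: c for c in model.chains}
        cands = scan_windows(torsions, chains)
        counts = [
            len(pair_strands(cands, model, cutoff=c)) for c in (2.0, 3.0, 3.5, 4.5, 6.0)
        ]
        assert counts == sorted(counts)


class TestDetect:
    def test_negative_control_pure_alpha(self):
        model, _ = generate_crick_coil(CrickParams(), 28)
        assert detect_beta_layers(model) == []

    def test_fixture_detected_exactly(self, nonad_fixture):
        model, ann = nonad_fixture
        layers = detect_beta_layers(model)
        assert len(layers) == 1
        planted = ann.planted_layers[0]
        for s in layers[0].strands:
            assert s.seq_ids == planted.strand_seq_ids
            assert s.sequence == planted.sequence

    def test_tandem_fixture_two_layers(self, tandem_fixture):
        model, ann = tandem_fixture
        layers = detect_beta_layers(model)
        assert len(layers) == 2
        assert [l.strands[0].seq_ids for l in layers] == [
            p.strand_seq_ids for p in ann.planted_layers
        ]

    def test_inflated_radius_yields_nothing(self, nonad_fixture):
        _, ann = nonad_fixture
        inflated, _ = generate_beta_layer_fixture(
            "nonad", bundle_radius=ann.bundle_radius + 3.0, seed=0
        )
        assert detect_beta_layers(inflated) == []

    def test_rigid_and_relabel_invariance(self, nonad_fixture, rng):
        model, _ = nonad_fixture
        base = detect_beta_layers(model)
        R, t = random_rigid_transform(rng)
        moved = model.transformed(R, t)
        relabeled = StructureModel(
            "m", [c.transformed(np.eye(3), np.zeros(3), chain_id=n)
                  for c, n in zip(moved.chains, "XYZ")],
        )
        layers = detect_beta_layers(relabeled)
        assert len(layers) == len(base) == 1
        assert [s.seq_ids for s in layers[0].strands] == [
            s.seq_ids for s in base[0].strands
        ]

    def test_battery_exact_recovery(self):
        """≥20 fixtures across spacings and seeds: exact central residues,
        and matching pure-α negative controls stay empty."""
        detected, total = 0, 0
        for spacing, seed in itertools.product(
            ("nonad", "hexad", "tandem-hexad"), range(7)
        ):
            model, ann = generate_beta_layer_fixture(
                spacing, seed=seed, n_flank=12 + seed % 5, jitter=0.5
            )
            layers = detect_beta_layers(model)
            total += 1
            found = sorted(l.strands[0].seq_ids[1] for l in layers)
            planted = sorted(p.strand_seq_ids[1] for p in ann.planted_layers)
            if found == planted and all(l.canonical for l in layers):
                detected += 1
        assert total >= 20
        assert detected == total

    def test_strict_trimer_filters_partial_layers(self, nonad_fixture):
        model, _ = nonad_fixture
        # drop one chain: the remaining two strands still pair (size 2)
        duo = StructureModel("duo", model.chains[:2])
        layers = detect_beta_layers(duo)
        assert len(layers) == 1 and layers[0].n_strands == 2
        assert not layers[0].canonical
        assert detect_beta_layers(duo, strict_trimer=True) == []


class TestAnnotation:
    @pytest.mark.parametrize(
        "strand_seq, expected",
        [("KAD", "C-cap"), ("MAT", "N-cap"), ("VYT", "N-cap"), ("SVR", "unclassified")],
    )
    def test_capping_rule(self, strand_seq, expected):
        classes = "aaaabbbaaaa"
        seq = "AAAA" + strand_seq + "AAAA"
        cands, chain = candidates_for(classes, sequence=seq)
        from betalayer.detector import BetaLayer

        layer = BetaLayer(strands=cands, hbonds=[])
        assert classify_capping(layer) == expected

    def test_transition_labels(self, nonad_fixture):
        model, _ = nonad_fixture
        layers = detect_beta_layers(model)
        assert layers[0].transition_type == "cc-to-cc"

    def test_transition_near_n_terminus(self):
        cands, chain = candidates_for("aabbbaaaa")
        ts = {"A": compute_torsions(chain)}
        from betalayer.detector import BetaLayer

        layer = BetaLayer(strands=cands, hbonds=[])
        assert annotate_transition(layer, ts) == "Nterm-to-cc"

    def test_transition_into_beta(self):
        # alpha upstream, beta run continuing downstream of the triplet
        classes = "aaaabbbbbb"
        cands, chain = candidates_for(classes)
        ts = {"A": compute_torsions(chain)}
        from betalayer.detector import BetaLayer

        first = [c for c in cands if c.indices[0] == brute_force_windows(classes)[0]]
        layer = BetaLayer(strands=first, hbonds=[])
        assert annotate_transition(layer, ts) == "cc-to-β"

    def test_register_strings_on_fixture(self, nonad_fixture):
        model, _ = nonad_fixture
        layers = detect_beta_layers(model)
        annotate_layer_registers(model, layers)
        assert layers[0].register_string == "a-b-c-β1-β2-β3-e-f-g"

    def test_report_table_columns(self, nonad_fixture):
        model, _ = nonad_fixture
        layers = detect_beta_layers(model)
        table = layers_to_table(layers)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["chains"] == "A,B,C"
        assert row["sequence"] == "MAT"
        assert bool(row["canonical"]) is True
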