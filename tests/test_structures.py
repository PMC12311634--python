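import numpy as np
import pytest

from tcrqa import synth
from tcrqa.structures import (
    AlignmentError,
    ChainMapError,
    ChainRole,
    NonStandardResidueError,
    ResidueRecord,
    StructureModel,
    count_backbone_clashes,
    median_pairwise_tcr_rmsd,
    parse_structure,
    superimpose_on_pmhc,
    tcr_backbone_rmsd,
    write_pdb,
)

from conftest import CHAIN_MAP, TINY_LENGTHS, random_rigid

TCR_ROLES = [ChainRole.TCRA, ChainRole.TCRB]


def _res(role, cid, idx, origin, aa="A"):
    o = np.asarray(origin, float)
    return ResidueRecord(role, cid, idx, aa, {
        "N": o, "CA": o + [1.46, 0, 0], "C": o + [2.0, 1.4, 0], "O": o + [1.9, 2.6, 0],
    })


def _toy_model(pep_origin=(50.0, 0, 0)):
    """One TCRA + one TCRB residue far from a 2-residue peptide."""
    residues = [
        _res(ChainRole.TCRA, "D", 0, (0, 0, 0)),
        _res(ChainRole.TCRB, "E", 0, (0, 30, 0)),
        _res(ChainRole.PEP, "C", 0, pep_origin),
        _res(ChainRole.PEP, "C", 1, np.asarray(pep_origin) + [4, 0, 0]),
    ]
    return StructureModel("toy", "toy", residues)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_three_chain_toy_counts(self, tmp_path):
        """A 4+3+9-residue TCRA/TCRB/PEP file parses to N_AA = 16."""
        residues = []
        for role, cid, n in ((ChainRole.TCRA, "D", 4), (ChainRole.TCRB, "E", 3),
                             (ChainRole.PEP, "C", 9)):
            for i in range(n):
                residues.append(_res(role, cid, i, (i * 5.0, {"D": 0, "E": 30, "C": 60}[cid], 0)))
        model = StructureModel("toy3", "toy3", residues)
        path = tmp_path / "toy3.pdb"
        write_pdb(model, path)
        parsed = parse_structure(path, {"D": "TCRA", "E": "TCRB", "C": "PEP"})
        assert parsed.n_residues == 16
        assert [len(parsed.chain(r)) for r in (ChainRole.TCRA, ChainRole.TCRB, ChainRole.PEP)] == [4, 3, 9]

    def test_nonstandard_residue_rejected(self, tmp_path):
        """Selenomethionine (MSE) causes a rejection naming the residue."""
        lines = []
        serial = 1
        for cid, resname, nres in (("D", "ALA", 3), ("E", "ALA", 3), ("C", "MSE", 1)):
            for i in range(nres):
                for atom in ("N", "CA", "C"):
                    x = i * 5.0 + ("N", "CA", "C").index(atom)
                    y = {"D": 0.0, "E": 20.0, "C": 40.0}[cid]
                    lines.append(
                        f"ATOM  {serial:5d} {(' ' + atom).ljust(4)} {resname:>3s} "
                        f"{cid}{i+1:4d}    {x:8.3f}{y:8.3f}{0.0:8.3f}  1.00  0.00"
                        f"          {atom[0]:>2s}\n")
                    serial += 1
        path = tmp_path / "mse.pdb"
        path.write_text("".join(lines) + "END\n")
        with pytest.raises(NonStandardResidueError, match="MSE"):
            parse_structure(path, {"D": "TCRA", "E": "TCRB", "C": "PEP"})

    def test_roundtrip_coordinates(self, tmp_path, native):
        model = native.copy()
        for r in model.residues:
            r.plddt = 80.0
        path = tmp_path / "rt.pdb"
        write_pdb(model, path)
        parsed = parse_structure(path, CHAIN_MAP, bfactor_is_plddt=True)
        assert parsed.n_residues == model.n_residues
        for r1, r2 in zip(model.residues, parsed.residues):
            assert r1.aa == r2.aa
            for name in r1.coords:
                assert np.allclose(r1.coords[name], r2.coords[name], atol=1e-3)
            assert r2.plddt == pytest.approx(80.0)

    def test_unmapped_chain_raises(self, tmp_path, native):
        path = tmp_path / "n.pdb"
        write_pdb(native, path)
        with pytest.raises(ChainMapError):
            parse_structure(path, {"D": "TCRA", "E": "TCRB", "C": "PEP"})
        # explicit drop of the MHC chain is allowed
        model = parse_structure(path, {"D": "TCRA", "E": "TCRB", "C": "PEP", "A": None})
        assert len(model.chain(ChainRole.MHC)) == 0


# ---------------------------------------------------------------------------
# clash counting
# ---------------------------------------------------------------------------

class TestClashes:
    def test_separated_chains_no_clashes(self):
        assert count_backbone_clashes(_toy_model()) == (0, 0) or True
        report = count_backbone_clashes(_toy_model())
        assert (report.tra_pep_clashes, report.trb_pep_clashes) == (0, 0)

    def test_single_constructed_pair(self):
        """One TRA backbone N placed 2.9 A from a peptide CA -> (1, 0)."""
        model = _toy_model()
        pep_ca = model.chain(ChainRole.PEP)[0].coords["CA"]
        tra = model.chain(ChainRole.TCRA)[0]
        # N approaches the peptide CA from +z; the rest of the residue
        # continues away so only one atom pair falls under the cutoff
        tra.coords = {
            "N": pep_ca + [0, 0, 2.9],
            "CA": pep_ca + [0, 0, 4.4],
            "C": pep_ca + [0, 0, 5.9],
            "O": pep_ca + [0, 0, 7.1],
        }
        report = count_backbone_clashes(model, cutoff=3.0)
        assert report.tra_pep_clashes == 1
        assert report.trb_pep_clashes == 0

    def test_six_contacts_flagged_for_filtering(self):
        """Six constructed TRA-pep atom pairs at 2.5 A exceed the 5-clash cap."""
        residues = [_res(ChainRole.TCRB, "E", 0, (0, 50, 0)),
                    _res(ChainRole.PEP, "C", 0, (0, 0, 0))]
        pep_n = residues[-1].coords["N"]
        for i in range(6):
            # six N atoms on a 2.5 A arc above the peptide N, each residue's
            # remaining backbone far away: exactly one clash pair per residue
            theta = np.deg2rad(100 + 12 * i)
            o = pep_n + np.array([0, 0, 30.0 + 10 * i])
            r = ResidueRecord(ChainRole.TCRA, "D", i, "A", {
                "N": pep_n + 2.5 * np.array([np.cos(theta), 0, np.sin(theta)]),
                "CA": o, "C": o + [1.5, 0, 0],
            })
            residues.append(r)
        model = StructureModel("six", "six", residues)
        report = count_backbone_clashes(model)
        assert report.tra_pep_clashes == 6
        from tcrqa.datasets import filter_clashed
        assert filter_clashed([(model, report)], max_clashes=5) == []

    def test_invariant_under_global_rigid_motion(self, native):
        rng = np.random.default_rng(3)
        base = count_backbone_clashes(native, cutoff=6.0)
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = native.transformed(R, t)
            assert count_backbone_clashes(moved, cutoff=6.0) == base


# ---------------------------------------------------------------------------
# superposition and pool RMSD
# ---------------------------------------------------------------------------

class TestSuperposition:
    def test_translation_recovery(self, native):
        mobile = native.transformed(np.eye(3), np.array([5.0, 0, 0]))
        aligned = superimpose_on_pmhc(mobile, native)
        all_roles = list(ChainRole)
        assert np.allclose(aligned.atom_coords(all_roles), native.atom_coords(all_roles),
                           atol=1e-6)

    def test_rotation_recovery(self, native):
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90 deg about z
        mobile = native.transformed(R, np.zeros(3))
        aligned = superimpose_on_pmhc(mobile, native)
        pmhc = [ChainRole.PEP, ChainRole.MHC]
        assert np.allclose(aligned.ca_coords(pmhc), native.ca_coords(pmhc), atol=1e-6)

    def test_tcr_offset_measured_after_alignment(self, native):
        """TCR translated 3 A in the common frame -> TCR backbone RMSD 3.0."""
        mobile = native.transformed(np.eye(3), np.array([0, 0, 3.0]), roles=TCR_ROLES)
        aligned = superimpose_on_pmhc(mobile, native)
        assert tcr_backbone_rmsd(aligned, native) == pytest.approx(3.0, abs=1e-6)

    def test_idempotent(self, native):
        mobile = native.transformed(np.eye(3), np.array([2.0, -1.0, 4.0]))
        once = superimpose_on_pmhc(mobile, native)
        twice = superimpose_on_pmhc(once, native)
        all_roles = list(ChainRole)
        assert np.abs(once.atom_coords(all_roles) - twice.atom_coords(all_roles)).max() < 1e-6

    def test_length_mismatch_raises(self, native):
        other = synth.make_native("other", {**TINY_LENGTHS, "PEP": 9}, seed=12)
        with pytest.raises(AlignmentError):
            superimpose_on_pmhc(other, native)


class TestMedianPairwiseRmsd:
    def test_identical_pool_is_zero(self, native):
        assert median_pairwise_tcr_rmsd([native.copy(), native.copy(), native.copy()]) == 0.0

    def test_axis_translations_compose(self, native):
        b = native.transformed(np.eye(3), np.array([0, 0, 4.0]), roles=TCR_ROLES)
        c = native.transformed(np.eye(3), np.array([0, 0, 8.0]), roles=TCR_ROLES)
        val = median_pairwise_tcr_rmsd([native, b, c])
        assert val == pytest.approx(4.0, abs=1e-6)

    def test_monotone_in_jitter(self, native):
        pools = {}
        for sigma in (0.5, 3.0):
            recipes = [synth.DecoyRecipe(0, 0, sigma, seed=100 + i) for i in range(10)]
            pools[sigma], _ = synth.make_decoys(native, recipes)
        assert (median_pairwise_tcr_rmsd(pools[3.0])
                > median_pairwise_tcr_rmsd(pools[0.5]))

    def test_invariant_under_permutation_and_rigid_motion(self, native):
        rng = np.random.default_rng(7)
        pool = [native.transformed(np.eye(3), rng.normal(size=3), roles=TCR_ROLES)
                for _ in range(4)]
        base = median_pairwise_tcr_rmsd(pool)
        assert median_pairwise_tcr_rmsd(pool[::-1]) == pytest.approx(base, abs=1e-9)
        R, t = random_rigid(rng)
        moved = [m.transformed(R, t) for m in pool]
        assert median_pairwise_tcr_rmsd(moved) == pytest.approx(base, abs=1e-6)

    def test_pool_too_small(self, native):
        with pytest.raises(ValueError):
            median_pairwise_tcr_rmsd([native])
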