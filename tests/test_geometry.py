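"""Pore geometry, Boltzmann profiles, restraint design and axial density.

Structure-based assertions use tolerances consistent with the
single-precision coordinate storage of the PDB container (well below
the 1e-3 A precision of the format itself).
"""

import math

import numpy as np
import pytest

from porefep import geometry as geo
from porefep import synthetic as syn
from porefep.exceptions import (
    DesignError,
    DomainError,
    MissingAtomsError,
    ValidationError,
)

PENTAGON_RADIUS = 15.0
PENTAGON_DISTANCE = 2 * PENTAGON_RADIUS * math.sin(2 * math.pi / 5)


def rotated(atoms, angle_deg=37.0):
    """Frame rigidly rotated about an oblique axis."""
    t = math.radians(angle_deg)
    axis = np.array([1.0, 2.0, 3.0])
    axis = axis / np.linalg.norm(axis)
    kmat = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + math.sin(t) * kmat + (1 - math.cos(t)) * kmat @ kmat
    out = atoms.copy()
    out.coord = atoms.coord @ rot.T.astype(np.float32)
    return out


class TestPoreCenter:
    def test_symmetric_pentamer_centers_on_axis(self, pentamer):
        center = geo.pore_center(pentamer)
        assert abs(center[0]) < 1e-5 and abs(center[1]) < 1e-5
        # anchors at z = -12 (res 226) and z = +15 (res 244)
        assert center[2] == pytest.approx(1.5, abs=1e-5)

    def test_translation_equivariance(self, pentamer):
        v = np.array([3.0, -2.0, 7.5], dtype=np.float32)
        moved = pentamer.copy()
        moved.coord = pentamer.coord + v
        assert np.allclose(
            geo.pore_center(moved), geo.pore_center(pentamer) + v, atol=1e-4
        )

    def test_missing_anchor_reported_with_location(self, pentamer):
        truncated = pentamer[~((pentamer.chain_id == "C") & (pentamer.res_id == 244))]
        with pytest.raises(MissingAtomsError, match="C.*244"):
            geo.pore_center(truncated)


class TestPoreAxis:
    def test_axis_is_z_for_upright_pentamer(self, pentamer):
        axis = geo.pore_axis(pentamer)
        assert abs(axis @ np.array([0.0, 0.0, 1.0])) > 1 - 1e-6
        # extracellular (residue 244) side positive
        assert axis[2] > 0

    def test_axis_follows_rigid_rotation(self, pentamer):
        rot = rotated(pentamer)
        axis = geo.pore_axis(rot)
        z226 = rot.coord[(rot.res_id == 226) & (rot.atom_name == "CA")].mean(axis=0)
        z244 = rot.coord[(rot.res_id == 244) & (rot.atom_name == "CA")].mean(axis=0)
        expected = z244 - z226
        expected = expected / np.linalg.norm(expected)
        assert axis @ expected == pytest.approx(1.0, abs=1e-6)


class TestM2PairDistances:
    def test_regular_pentagon_identity(self, pentamer):
        series = geo.m2_pair_distances(pentamer)
        assert series.pair_labels == ("1-3", "1-4", "2-4", "2-5", "3-5")
        assert np.allclose(series.values, PENTAGON_DISTANCE, atol=1e-4)

    def test_rigid_rotation_leaves_distances_unchanged(self, pentamer):
        before = geo.m2_pair_distances(pentamer).values
        after = geo.m2_pair_distances(rotated(pentamer)).values
        assert np.allclose(before, after, atol=1e-3)

    def test_single_subunit_collapse_shrinks_exactly_its_pairs(self):
        collapsed = syn.gen_pentamer_structure(collapse_chain="C", collapse_by=3.0)
        series = geo.m2_pair_distances(collapsed)
        vals = dict(zip(series.pair_labels, series.values[0]))
        # chain C is position 3 around the ring
        for label in ("1-3", "3-5"):
            assert vals[label] < PENTAGON_DISTANCE - 1.0
        for label in ("1-4", "2-4", "2-5"):
            assert vals[label] == pytest.approx(PENTAGON_DISTANCE, abs=1e-4)

    def test_multi_frame_shape_and_pooling(self, pentamer):
        series = geo.m2_pair_distances([pentamer, pentamer, pentamer])
        assert series.values.shape == (3, 5)
        assert series.pooled().shape == (15,)


class TestBoltzmannProfile:
    def test_gaussian_samples_give_harmonic_profile(self, ctx):
        sigma = 0.5
        samples = np.random.default_rng(5).normal(20.0, sigma, 100_000)
        prof = geo.boltzmann_profile(samples, bin_width=0.1, ctx=ctx)
        mask = prof.defined & (np.abs(prof.centers - 20.0) < 1.0)
        curvature = 2.0 * np.polyfit(prof.centers[mask], prof.values[mask], 2)[0]
        assert curvature == pytest.approx(ctx.kt / sigma**2, rel=0.1)

    def test_uniform_samples_give_flat_profile(self, ctx):
        samples = np.random.default_rng(0).uniform(0.0, 10.0, 200_000)
        prof = geo.boltzmann_profile(samples, bin_width=0.5, ctx=ctx)
        v = prof.values[prof.defined]
        sigma_counting = ctx.kt / math.sqrt(200_000 * 0.5 / 10.0)
        assert np.max(np.abs(v - v.mean())) < 3.0 * sigma_counting

    def test_bimodal_mixture_shows_two_minima_and_barrier(self, ctx):
        samples = syn.gen_distance_series(n=100_000, seed=3)
        prof = geo.boltzmann_profile(samples, bin_width=0.1, ctx=ctx)
        v, c = prof.values, prof.centers
        i_open = np.nanargmin(np.where(np.abs(c - 20.0) < 0.4, v, np.inf))
        i_coll = np.nanargmin(np.where(np.abs(c - 18.5) < 0.4, v, np.inf))
        between = v[min(i_open, i_coll) + 1 : max(i_open, i_coll)]
        assert np.nanmax(between) > v[i_open] and np.nanmax(between) > v[i_coll]

    def test_duplication_invariance(self, ctx):
        samples = np.random.default_rng(1).normal(20.0, 0.5, 5000)
        prof1 = geo.boltzmann_profile(samples, bin_width=0.2, ctx=ctx, bounds=(18, 22))
        prof2 = geo.boltzmann_profile(
            np.concatenate([samples, samples]), bin_width=0.2, ctx=ctx, bounds=(18, 22)
        )
        assert np.allclose(prof1.values, prof2.values, equal_nan=True, atol=1e-12)

    def test_empty_bins_flagged_not_zeroed(self, ctx):
        samples = np.concatenate([np.full(100, 1.0), np.full(100, 5.0)])
        prof = geo.boltzmann_profile(samples, bin_width=0.5, ctx=ctx, bounds=(0, 6))
        assert np.isnan(prof.values[~prof.defined]).all()
        assert (~prof.defined).sum() > 0

    def test_zero_bin_width_rejected(self, ctx):
        with pytest.raises(ValidationError):
            geo.boltzmann_profile(np.ones(10), bin_width=0.0, ctx=ctx)


class TestRestraintDesign:
    def test_wall_lands_on_barrier_side_of_open_basin(self, ctx):
        samples = syn.gen_distance_series(n=100_000, seed=3)
        prof = geo.boltzmann_profile(samples, bin_width=0.1, ctx=ctx)
        spec = geo.design_flat_bottom_restraint(prof, open_basin_center=20.0, ctx=ctx)
        assert 19.0 <= spec.d0 <= 19.6
        assert spec.k == 10.0

    def test_single_well_profile_raises_design_error(self, ctx):
        samples = np.random.default_rng(2).normal(20.0, 0.4, 50_000)
        prof = geo.boltzmann_profile(samples, bin_width=0.1, ctx=ctx)
        with pytest.raises(DesignError) as err:
            geo.design_flat_bottom_restraint(prof, open_basin_center=20.0, ctx=ctx)
        assert err.value.profile is prof

    def test_flat_bottom_region_has_zero_energy_and_force(self):
        spec = geo.RestraintSpec(d0=19.3, k=10.0)
        d = np.linspace(19.3, 25.0, 50)
        assert np.all(spec.energy(d) == 0.0)
        assert np.all(spec.force(d) == 0.0)

    def test_wall_side_is_harmonic(self):
        spec = geo.RestraintSpec(d0=19.3, k=10.0)
        assert spec.energy(18.3) == pytest.approx(5.0, rel=1e-12)
        assert spec.force(18.3) == pytest.approx(10.0, rel=1e-12)

    def test_continuity_at_wall(self):
        spec = geo.RestraintSpec(d0=19.3, k=10.0)
        h = 1e-6
        assert spec.energy(spec.d0 - h) < 1e-11
        # first derivative continuous: central difference ~ 0 at d0
        deriv = (spec.energy(spec.d0 + h) - spec.energy(spec.d0 - h)) / (2 * h)
        assert abs(deriv) < 1e-5


class TestAxialDensity:
    def test_point_mass_spreads_over_three_bins(self):
        z = np.full(500, 3.2)
        prof = geo.axial_density(z, n_ligands=1, bin_width=0.5, bounds=(0, 10))
        assert (prof.rho > 0).sum() == 3
        assert prof.rho.sum() * prof.bin_width == pytest.approx(1.0, abs=1e-9)

    def test_uniform_two_ligand_density_integrates_to_two(self):
        z = np.random.default_rng(4).uniform(-10, 10, 100_000)
        prof = geo.axial_density(z, n_ligands=2, bin_width=0.5, bounds=(-10, 10))
        assert prof.rho.sum() * prof.bin_width == pytest.approx(2.0, abs=1e-9)
        interior = prof.rho[2:-2]
        assert np.max(np.abs(interior - 0.1)) < 0.01

    @pytest.mark.parametrize("n_ligands", [1, 2])
    def test_conservation_before_and_after_smoothing(self, n_ligands):
        z = np.random.default_rng(8).normal(0.0, 2.0, 5000)
        prof = geo.axial_density(z, n_ligands=n_ligands, bin_width=0.5)
        assert prof.rho_raw.sum() * prof.bin_width == pytest.approx(n_ligands, abs=1e-6)
        assert prof.rho.sum() * prof.bin_width == pytest.approx(n_ligands, abs=1e-6)

    def test_two_well_peaks_at_well_centers(self, ctx):
        model = syn.PoreToyModel(
            site_centers=[-4.0, 4.0], well_depths=[5.0, 5.0], well_widths=[1.0, 1.0],
            n_frames=20_000, seed=12,
        )
        z = syn.gen_pore_trajectory(model, ctx)
        prof = geo.axial_density(z.ravel(), n_ligands=1, bin_width=0.5)
        for center in (-4.0, 4.0):
            window = np.abs(prof.centers - center) <= 1.5
            peak = prof.centers[window][np.argmax(prof.rho[window])]
            assert abs(peak - center) <= 0.5 + 1e-9  # within one bin

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            geo.axial_density(np.array([]), n_ligands=1)
        with pytest.raises(ValidationError):
            geo.axial_density(np.ones(5), n_ligands=3)


class TestPrimeNotation:
    @pytest.mark.parametrize("residue, prime", [(232, 9), (239, 16), (226, 3)])
    def test_anchor_mapping(self, residue, prime):
        assert geo.prime_index(residue) == prime
        assert geo.residue_for_prime(prime) == residue

    @pytest.mark.parametrize("residue", [200, 260])
    def test_out_of_span_rejected(self, residue):
        with pytest.raises(DomainError):
            geo.prime_index(residue)


class TestSiteOccupancy:
    def sites(self):
        return [
            geo.SiteDefinition("secondary_lower", (6, 9), (-9.0, -4.5)),
            geo.SiteDefinition("primary", (9, 16), (-4.5, 6.0)),
            geo.SiteDefinition("secondary_upper", (16, 20), (6.0, 12.0)),
        ]

    def test_all_density_in_primary(self):
        z = np.random.default_rng(1).uniform(-4.0, 5.5, 2000)
        occ = geo.site_occupancy(z, self.sites(), n_ligands=2)
        assert occ["primary"] == pytest.approx(2.0)
        assert occ["secondary_lower"] == 0.0 and occ["secondary_upper"] == 0.0

    def test_tiling_sites_conserve_ligand_count(self):
        z = np.random.default_rng(2).uniform(-9.0, 12.0, 20_000)
        occ = geo.site_occupancy(z, self.sites(), n_ligands=2)
        assert sum(occ.values()) == pytest.approx(2.0, abs=1e-9)

    def test_profile_based_occupancy_matches_sample_based(self):
        z = np.random.default_rng(3).normal(0.0, 3.0, 50_000)
        prof = geo.axial_density(z, n_ligands=1, bin_width=0.25, bounds=(-10, 13))
        occ_prof = geo.site_occupancy(prof, self.sites())
        occ_samp = geo.site_occupancy(z, self.sites(), n_ligands=1)
        for label in occ_samp:
            assert occ_prof[label] == pytest.approx(occ_samp[label], abs=0.01)

    def test_overlapping_sites_rejected(self):
        bad = [
            geo.SiteDefinition("a", (6, 9), (-5.0, 0.0)),
            geo.SiteDefinition("b", (9, 16), (-1.0, 4.0)),
        ]
        with pytest.raises(ValidationError):
            geo.site_occupancy(np.zeros(10), bad, n_ligands=1)

    def test_sites_from_structure_geometry(self, pentamer):
        sites = {s.label: s for s in geo.sites_from_structure(pentamer)}
        # residues stack at 1.5 A per residue; pore center at z = 1.5
        assert sites["primary"].z_interval == pytest.approx((-4.5, 6.0), abs=1e-4)
        assert sites["secondary_lower"].z_interval[1] == pytest.approx(-4.5, abs=1e-4)
        assert sites["secondary_upper"].z_interval[0] == pytest.approx(6.0, abs=1e-4)


class TestPdbRoundTrip:
    def test_distances_survive_write_read(self, pentamer, tmp_path):
        path = tmp_path / "pentamer.pdb"
        geo.write_pdb(pentamer, path)
        reread = geo.read_pdb(path)
        before = geo.m2_pair_distances(pentamer).values
        after = geo.m2_pair_distances(reread).values
        assert np.allclose(before, after, atol=5e-3)  # PDB prints 1e-3 A
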