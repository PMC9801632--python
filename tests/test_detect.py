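"""Detector contracts, including exact equivalence with brute-force
flood-fill labeling and greedy regional-maxima enumeration on small images."""
import numpy as np
import pytest

from axonquant import (GroundTruth, SimulationConfig, cell_params, detect_axons,
                       detect_boutons, detect_cells, estimate_background,
                       generate_vta_section, max_project, params_10x, params_25x,
                       render_section)
from axonquant.detect import log_response

PS = 0.62  # µm/px used throughout unless a test says otherwise


# ---------------------------------------------------------------------------
# brute-force oracles

def flood_fill_components(mask):
    """8-connected component labeling by explicit BFS."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = nxt
                                stack.append((rr, cc))
    return labels


def greedy_maxima(response, mask, min_distance):
    """Regional maxima inside ``mask``, greedily accepted in decreasing
    response order with a hard minimum separation — the defining rule for
    splitting touching puncta."""
    cand = []
    h, w = response.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            v = response[r, c]
            neigh = response[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            if v >= neigh.max():
                cand.append((v, r, c))
    cand.sort(reverse=True)
    accepted = []
    for v, r, c in cand:
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_distance**2
               for ar, ac in accepted):
            accepted.append((r, c))
    return sorted(accepted)


# ---------------------------------------------------------------------------

class TestBackground:
    def test_constant_image(self):
        bg = estimate_background(np.full((64, 64), 100.0))
        assert (bg.mean, bg.sd) == (100.0, 0.0)

    def test_gaussian_noise(self):
        rng = np.random.default_rng(0)
        img = rng.normal(50, 5, size=(512, 512))
        bg = estimate_background(img)
        assert bg.mean == pytest.approx(50, rel=0.02)
        assert bg.sd == pytest.approx(5, rel=0.02)

    def test_robust_to_bright_contamination(self):
        rng = np.random.default_rng(1)
        img = rng.normal(50, 5, size=(512, 512))
        n = img.size // 100
        idx = rng.choice(img.size, n, replace=False)
        img.ravel()[idx] = 10000.0
        bg = estimate_background(img)
        assert bg.mean == pytest.approx(50, rel=0.05)
        assert bg.sd == pytest.approx(5, rel=0.05)

    def test_empty_and_tiny_roi_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            estimate_background(img, np.zeros((32, 32), bool))
        tiny = np.zeros((32, 32), bool)
        tiny[0, :10] = True
        with pytest.raises(ValueError):
            estimate_background(img, tiny)


class TestAxonDetector:
    def test_pure_noise_false_positive_rate(self, default_config):
        red, _ = render_section(GroundTruth(region_label="BLA"), default_config,
                                rng=np.random.default_rng(7))
        det = detect_axons(max_project(red), None, params_10x(), PS)
        assert det.axon_pixel_count <= 0.001 * red.data[0].size

    def test_straight_bar_length(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 1, size=(200, 200))
        img[100:103, 20:170] += 100.0  # 3 px wide, 150 px long
        det = detect_axons(img, None, params_10x(), PS)
        assert det.axon_pixel_count == pytest.approx(150, abs=3)

    def test_simulated_length_recovery(self, bla_section):
        truth, red, _ = bla_section
        det = detect_axons(max_project(red), None, params_10x(), PS)
        est = det.axon_pixel_count * PS
        assert est == pytest.approx(truth.total_axon_length_um, rel=0.15)

    def test_skeleton_subset_and_unit_width(self, bla_section):
        _, red, _ = bla_section
        det = detect_axons(max_project(red), None, params_10x(), PS)
        assert not (det.skeleton_mask & ~det.binary_mask).any()
        s = det.skeleton_mask
        blocks = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        assert not blocks.any()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            detect_axons(np.zeros((64, 64)), np.zeros((64, 64), bool),
                         params_10x(), PS)


def _two_spot_image(sep_px, sigma_px=2.0, shape=(96, 96), amp=200.0):
    rng = np.random.default_rng(5)
    img = rng.normal(10, 1, size=shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for dx in (-sep_px / 2, sep_px / 2):
        cx, cy = shape[1] / 2 + dx, shape[0] / 2
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
    return img


class TestBoutonDetector:
    def test_single_spot(self):
        img = _two_spot_image(0.0)
        det = detect_boutons(img, None, params_25x(), 0.25)
        assert det.count == 1
        r, c = det.centers_px[0]
        assert abs(r - 48) <= 1 and abs(c - 48) <= 1

    @pytest.mark.parametrize("sep_sigma,expected", [(4.0, 2), (0.5, 1)])
    def test_touching_spots_split_by_separation(self, sep_sigma, expected):
        sigma_px = 2.0
        img = _two_spot_image(sep_sigma * sigma_px, sigma_px=sigma_px)
        det = detect_boutons(img, None, params_25x(), 0.25)
        assert det.count == expected

    def test_simulated_count_recovery(self, sparse_bouton_section):
        cfg, truth, _, green = sparse_bouton_section
        det = detect_boutons(max_project(green), None, params_10x(),
                             cfg.pixel_size_um)
        assert det.count == pytest.approx(truth.n_boutons, rel=0.10)

    def test_recall_precision_on_default_snr(self, sparse_bouton_section):
        from scipy.spatial import cKDTree
        cfg, truth, _, green = sparse_bouton_section
        det = detect_boutons(max_project(green), None, params_10x(),
                             cfg.pixel_size_um)
        det_um = np.c_[det.centers_px[:, 1], det.centers_px[:, 0]] * cfg.pixel_size_um
        d_truth, _ = cKDTree(det_um).query(truth.bouton_centers_um)
        recall = (d_truth < 1.5).mean()
        d_det, _ = cKDTree(truth.bouton_centers_um).query(det_um)
        precision = (d_det < 1.5).mean()
        assert recall >= 0.9 and precision >= 0.9

    def test_noise_only_few_false_positives(self, default_config):
        _, green = render_section(GroundTruth(region_label="BLA"), default_config,
                                  rng=np.random.default_rng(8))
        det = detect_boutons(max_project(green), None, params_10x(), PS)
        assert det.count <= 10


class TestCellDetector:
    def _render_discs(self, areas_xy, cfg=None):
        cfg = cfg or SimulationConfig(seed=0)
        truth = GroundTruth(soma_centers_um=np.asarray(areas_xy), region_label="VTA")
        _, green = render_section(truth, cfg, rng=np.random.default_rng(2))
        return cfg, truth, max_project(green)

    def test_disc_in_range_counted(self):
        cfg, _, img = self._render_discs([[80.0, 80.0, 100.0]])
        det = detect_cells(img, None, cell_params(), cfg.pixel_size_um)
        assert det.count == 1

    def test_disc_below_gate_removed(self):
        cfg, _, img = self._render_discs([[80.0, 80.0, 30.0]])
        det = detect_cells(img, None, cell_params(), cfg.pixel_size_um)
        assert det.count == 0

    def test_twelve_discs_counted_with_matching_centers(self):
        from scipy.spatial import cKDTree
        rng = np.random.default_rng(9)
        rows = []
        for i in range(12):
            x = 25.0 + (i % 4) * 36.0
            y = 25.0 + (i // 4) * 50.0
            rows.append([x, y, float(rng.uniform(70, 180))])
        cfg, truth, img = self._render_discs(rows)
        det = detect_cells(img, None, cell_params(), cfg.pixel_size_um)
        assert det.count == 12
        cen = np.array([[c[0][1], c[0][0]] for c in det.components]) * cfg.pixel_size_um
        d, _ = cKDTree(cen).query(truth.soma_centers_um[:, :2])
        assert (d < 3.0).all()

    def test_retained_areas_respect_minimum(self, default_config):
        _, green, truth = generate_vta_section(30, default_config,
                                               rng=np.random.default_rng(3))
        det = detect_cells(max_project(green), None, cell_params(), PS)
        assert all(c[1] >= 49.0 for c in det.components)

    def test_recall_on_default_snr_sections(self, default_config):
        true = det = 0
        for seed in (5, 6, 7, 8):
            _, green, truth = generate_vta_section(30, default_config,
                                                   rng=np.random.default_rng(seed))
            true += truth.n_somata
            det += detect_cells(max_project(green), None, cell_params(), PS).count
        assert det / true >= 0.9
        assert det / true <= 1.1  # precision: no systematic over-count


class TestDetectorProperties:
    def test_threshold_monotonicity(self, bla_section, default_config):
        """Raising the SD threshold never increases any detection count."""
        truth, red, green = bla_section
        _, vta_green, _ = generate_vta_section(25, default_config,
                                               rng=np.random.default_rng(13))
        vta_img = max_project(vta_green)
        red_img, green_img = max_project(red), max_project(green)
        prev = (np.inf, np.inf, np.inf)
        for k in (3.0, 5.0, 7.0, 9.0):
            counts = (
                detect_axons(red_img, None, params_10x(threshold_sd=k), PS).axon_pixel_count,
                detect_boutons(green_img, None, params_10x(threshold_sd=k), PS).count,
                detect_cells(vta_img, None, cell_params(threshold_sd=k), PS).count,
            )
            assert all(c <= p for c, p in zip(counts, prev))
            prev = counts

    def test_intensity_shift_invariance(self, bla_section):
        truth, red, green = bla_section
        red_img, green_img = max_project(red), max_project(green)
        for img, detect, key in ((red_img, detect_axons, "axon_pixel_count"),
                                 (green_img, detect_boutons, "count")):
            base = getattr(detect(img, None, params_10x(), PS), key)
            shifted = getattr(detect(img + 500.0, None, params_10x(), PS), key)
            assert base == shifted

    def test_component_labeling_matches_flood_fill(self):
        """On a small image, the thresholded-response component structure is
        exactly the brute-force BFS labeling."""
        from skimage.measure import label as sk_label
        rng = np.random.default_rng(4)
        img = rng.normal(10, 1, size=(48, 48))
        for _ in range(6):
            cx, cy = rng.uniform(8, 40, 2)
            yy, xx = np.mgrid[0:48, 0:48]
            img += 150 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.5**2))
        resp = log_response(img, 1.5)
        bg = estimate_background(resp)
        mask = resp > bg.mean + 5 * bg.sd
        ours = sk_label(mask, connectivity=2)
        brute = flood_fill_components(mask)
        # identical partitions up to label permutation
        pairs = {(a, b) for a, b in zip(ours.ravel(), brute.ravel())}
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})

    def test_peak_splitting_matches_greedy_enumeration(self):
        """Detector bouton centers equal the greedy decreasing-response
        maxima enumeration on a small two-spot image."""
        img = _two_spot_image(8.0, sigma_px=2.0, shape=(64, 64))
        det = detect_boutons(img, None, params_25x(), 0.25)
        sigma_px = params_25x().log_sigma_um / 0.25
        resp = log_response(img, sigma_px)
        bg = estimate_background(resp)
        mask = resp > bg.mean + 7 * bg.sd
        min_dist = max(1, round(params_25x().bouton_diameter_um / 0.25))
        expected = greedy_maxima(resp, mask, min_dist)
        assert sorted(map(tuple, det.centers_px.tolist())) == expected
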