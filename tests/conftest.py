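import numpy as np
import pytest

from mammocad import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(rng_seed=7))


@pytest.fixture()
def disk_mask():
    def make(radius: int, size: int | None = None, intensity: int = 200):
        size = size or (2 * radius + 20)
        rr, cc = np.mgrid[0:size, 0:size]
        center = size // 2
        mask = (rr - center) ** 2 + (cc - center) ** 2 <= radius**2
        image = np.where(mask, intensity, 0).astype(np.uint8)
        return mask, image

    return make


def bfs_flood_fill(img, seed, threshold, connectivity):
    """Brute-force seeded flood fill; independent oracle for region growing."""
    img = np.asarray(img)
    h, w = img.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    mask = np.zeros((h, w), dtype=bool)
    stack = [seed]
    mask[seed] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in steps:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] \
                    and img[nr, nc] >= threshold:
                mask[nr, nc] = True
                stack.append((nr, nc))
    return mask
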