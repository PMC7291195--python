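import numpy as np
import pytest

from gliaclone import CellSkeleton


def make_skeleton(nodes):
    """Build a skeleton from (id, type, x, y, z, radius, parent) tuples."""
    arr = np.array([n[2:6] for n in nodes], dtype=float)
    return CellSkeleton(
        ids=np.array([n[0] for n in nodes]),
        types=np.array([n[1] for n in nodes]),
        xyz=arr[:, :3],
        radius=arr[:, 3],
        parent=np.array([n[6] for n in nodes]),
    )


@pytest.fixture
def straight_path_skeleton():
    """Soma at origin plus a straight unbranched 10 µm process along +x."""
    nodes = [(1, 1, 0, 0, 0, 1.0, -1)]
    for k in range(1, 6):
        nodes.append((k + 1, 0, 2.0 * k, 0, 0, 0.5, k))
    return make_skeleton(nodes)


@pytest.fixture
def bifurcating_skeleton():
    """One primary process forking at 5 µm into two children reaching 12 µm."""
    return make_skeleton(
        [
            (1, 1, 0, 0, 0, 1.0, -1),
            (2, 0, 5, 0, 0, 0.5, 1),
            (3, 0, 12, 0, 0, 0.4, 2),
            (4, 0, 0, 12, 0, 0.4, 2),
        ]
    )


def random_outward_tree(rng, n_branch_events=8, step=2.0, max_extent=30.0):
    """Random rooted tree growing radially outward (monotone node distances)."""
    nodes = [(1, 1, 0.0, 0.0, 0.0, 1.5, -1)]
    tips = []
    for _ in range(int(rng.integers(2, 5))):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = d * 1.5
        nid = len(nodes) + 1
        nodes.append((nid, 0, *pos, 0.4, 1))
        tips.append((nid, pos, d))
    events = 0
    while tips:
        nid, pos, d = tips.pop(0)
        if np.linalg.norm(pos) >= max_extent:
            continue
        nd = d + 0.25 * rng.normal(size=3) + 0.3 * pos / max(np.linalg.norm(pos), 1e-9)
        nd /= np.linalg.norm(nd)
        npos = pos + nd * step
        if np.dot(pos, npos - pos) < 0:  # keep distance monotone along segments
            continue
        new_id = len(nodes) + 1
        nodes.append((new_id, 0, *npos, 0.4, nid))
        tips.append((new_id, npos, nd))
        if events < n_branch_events and rng.random() < 0.25:
            events += 1
            sd = nd + 0.8 * rng.normal(size=3)
            sd /= np.linalg.norm(sd)
            spos = pos + sd * step
            if np.dot(pos, spos - pos) >= 0:
                sid = len(nodes) + 1
                nodes.append((sid, 0, *spos, 0.4, nid))
                tips.append((sid, spos, sd))
    return make_skeleton(nodes)
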