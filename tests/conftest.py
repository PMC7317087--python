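import pytest

from biotracks import (
    BiotracksPackage,
    Link,
    TrackedObject,
    infer_tracks,
)


def make_objects(frames_xy, start_id=0):
    """Build TrackedObjects from (frame, x, y) triples with sequential ids."""
    return [TrackedObject(object_id=start_id + i, frame=f, x=float(x), y=float(y))
            for i, (f, x, y) in enumerate(frames_xy)]


@pytest.fixture
def straight_line_package():
    """One 3-4-5 step: (0,0) -> (3,4) over one frame."""
    objects = make_objects([(0, 0, 0), (1, 3, 4)])
    links = [Link(0, (0, 1))]
    pkg = BiotracksPackage(objects=objects, links=links)
    pkg.tracks = infer_tracks(objects, links)
    return pkg


@pytest.fixture
def square_loop_package():
    """A unit square walked back to the origin (net displacement 0)."""
    corners = [(0, 0, 0), (1, 1, 0), (2, 1, 1), (3, 0, 1), (4, 0, 0)]
    objects = make_objects(corners)
    links = [Link(0, tuple(range(5)))]
    pkg = BiotracksPackage(objects=objects, links=links)
    pkg.tracks = infer_tracks(objects, links)
    return pkg


@pytest.fixture
def split_package():
    """One parent dividing into two daughters at object 1."""
    objects = make_objects([(0, 0, 0), (1, 1, 0), (2, 2, 1), (3, 3, 2),
                            (2, 2, -1), (3, 3, -2)])
    links = [Link(0, (0, 1)), Link(1, (1, 2, 3)), Link(2, (1, 4, 5))]
    pkg = BiotracksPackage(objects=objects, links=links)
    pkg.tracks = infer_tracks(objects, links)
    return pkg


def brute_force_components(links):
    """Oracle: naive DFS connected components of the object-sharing graph.

    Independent of the production path (no networkx): adjacency is
    link-to-link object sharing, explored with an explicit stack.
    """
    ids = [ln.link_id for ln in links]
    members = {ln.link_id: set(ln.object_ids) for ln in links}
    unvisited = set(ids)
    components = []
    for seed in ids:
        if seed not in unvisited:
            continue
        component = set()
        stack = [seed]
        unvisited.discard(seed)
        while stack:
            current = stack.pop()
            component.add(current)
            for other in list(unvisited):
                if members[current] & members[other]:
                    unvisited.discard(other)
                    stack.append(other)
        components.append(frozenset(component))
    return sorted(components, key=min)
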