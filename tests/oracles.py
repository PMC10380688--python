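"""Independent brute-force reference detectors.

Plain O(n^2)/O(n^3) loops over every candidate pair/triple, written against
the detection rules directly (law-of-cosines angles, Pythagorean in-plane
offsets) and kept free of any code from trajcontacts.detect.  The detector
tests assert exact set equality between these and the package detectors.
"""

from __future__ import annotations

import math


def _dist(a, b) -> float:
    return math.dist(tuple(a), tuple(b))


def _angle_at(vertex, p, q) -> float:
    """Angle p-vertex-q in degrees via the law of cosines."""
    a = _dist(vertex, p)
    b = _dist(vertex, q)
    c = _dist(p, q)
    cosc = (a * a + b * b - c * c) / (2 * a * b)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosc))))


def _role(frame, serial):
    return frame.by_serial[serial].role.value


def _is_lig(frame, s):
    return _role(frame, s) == "ligand"


def _is_rcpt(frame, s):
    return _role(frame, s).startswith("receptor")


def oracle_hbonds(frame, perception, c) -> set:
    """All donor-acceptor pairs, one side ligand; same dedup as the detector."""
    found = {}
    for d, hs in perception.donors.items():
        for a in perception.acceptors:
            if a == d:
                continue
            lig, rcpt = None, None
            if _is_lig(frame, d) and _is_rcpt(frame, a):
                lig, rcpt, protisdon = d, a, False
            elif _is_rcpt(frame, d) and _is_lig(frame, a):
                lig, rcpt, protisdon = a, d, True
            else:
                continue
            da = _dist(frame.coords_of(d), frame.coords_of(a))
            if da < c.min_pair_dist:
                continue
            if hs:
                if da > c.hbond_max_da_dist:
                    continue
                best = max(_angle_at(frame.coords_of(h), frame.coords_of(d),
                                     frame.coords_of(a)) for h in hs)
                if best < c.hbond_min_dha_angle:
                    continue
            elif da > c.hbond_heavy_only_max_dist:
                continue
            key = ("hbond", (lig,), (rcpt,), None)
            if key not in found or (found[key] and not protisdon):
                found[key] = protisdon
    return set(found)


def oracle_hydrophobic(frame, perception, c) -> set:
    best = {}
    for ls in perception.hydrophobic:
        if not _is_lig(frame, ls):
            continue
        for rs in perception.hydrophobic:
            if not _is_rcpt(frame, rs):
                continue
            d = _dist(frame.coords_of(ls), frame.coords_of(rs))
            if not (c.min_pair_dist <= d <= c.hydrophobic_max_dist):
                continue
            res = frame.by_serial[rs].residue_id
            if (ls, res) not in best or (d, rs) < best[(ls, res)]:
                best[(ls, res)] = (d, rs)
    return {("hydrophobic", (ls,), (rs,), None)
            for (ls, _res), (_d, rs) in best.items()}


def oracle_pi_stacks(frame, perception, c) -> set:
    out = set()
    for lr in perception.rings:
        if lr.role.value != "ligand":
            continue
        for rr in perception.rings:
            if not rr.role.value.startswith("receptor"):
                continue
            d = _dist(lr.centroid, rr.centroid)
            if d < c.min_pair_dist or d > c.pistack_max_centroid_dist:
                continue
            dot = sum(x * y for x, y in zip(lr.normal, rr.normal))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, abs(dot)))))
            delta = [b - a for a, b in zip(lr.centroid, rr.centroid)]
            offs = []
            for normal in (lr.normal, rr.normal):
                along = sum(x * y for x, y in zip(delta, normal))
                offs.append(math.sqrt(max(0.0, d * d - along * along)))
            if min(offs) > c.pistack_max_offset:
                continue
            if not (theta <= c.pistack_parallel_max_angle
                    or theta >= c.pistack_tshaped_min_angle):
                continue
            out.add(("pi_stack", tuple(sorted(lr.member_serials)),
                     tuple(sorted(rr.member_serials)), None))
    return out


def oracle_salt_bridges(frame, perception, c) -> set:
    out = set()
    for lg in perception.charged_groups:
        if lg.role.value != "ligand":
            continue
        for rg in perception.charged_groups:
            if not rg.role.value.startswith("receptor"):
                continue
            if lg.charge_sign == rg.charge_sign:
                continue
            d = _dist(lg.center, rg.center)
            if c.min_pair_dist <= d <= c.saltbridge_max_dist:
                out.add(("salt_bridge", tuple(sorted(lg.member_serials)),
                         tuple(sorted(rg.member_serials)), None))
    return out


def oracle_water_bridges(frame, perception, c) -> set:
    lig_polar = [s for s in set(perception.donors) | perception.acceptors
                 if _is_lig(frame, s)]
    rcpt_polar = [s for s in set(perception.donors) | perception.acceptors
                  if _is_rcpt(frame, s)]
    out = set()
    for w in perception.water_oxygens:
        for ls in lig_polar:
            dlw = _dist(frame.coords_of(ls), frame.coords_of(w))
            if not (c.waterbridge_min_dist <= dlw <= c.waterbridge_max_dist):
                continue
            for rs in rcpt_polar:
                drw = _dist(frame.coords_of(rs), frame.coords_of(w))
                if not (c.waterbridge_min_dist <= drw <= c.waterbridge_max_dist):
                    continue
                pair_ok = (ls in perception.donors and rs in perception.acceptors) \
                    or (rs in perception.donors and ls in perception.acceptors)
                if pair_ok:
                    out.add(("water_bridge", (ls,), (rs,), w))
    return out


def oracle_all(frame, perception, c) -> set:
    return (oracle_hbonds(frame, perception, c)
            | oracle_hydrophobic(frame, perception, c)
            | oracle_pi_stacks(frame, perception, c)
            | oracle_salt_bridges(frame, perception, c)
            | oracle_water_bridges(frame, perception, c))
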