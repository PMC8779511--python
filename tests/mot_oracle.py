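"""Independent brute-force CLEAR-MOT counter used as a test oracle.

Per frame it keeps still-valid correspondences from earlier frames, then
enumerates every injective assignment of the remaining ground-truth boxes
to hypothesis boxes (gated at the IoU threshold), choosing the one that
maximizes the number of matches and, among those, minimizes the total
(1 - IoU) cost. Exponential, so only for tiny scenes; deliberately shares
no code with the package's Hungarian-based implementation.
"""

from itertools import permutations


def brute_force_mot(gt_by_frame, hyp_by_frame, iou_match=0.5, iou_fn=None):
    """gt_by_frame / hyp_by_frame: frame -> list of (object_id, box).

    ``iou_fn(box_a, box_b)`` defaults to ``box_a.iou(box_b)``.
    Returns (gt, fn, fp, idsw).
    """
    if iou_fn is None:
        iou_fn = lambda a, b: a.iou(b)

    n_gt = n_fn = n_fp = n_idsw = 0
    last = {}  # gt id -> hyp id

    for frame in sorted(set(gt_by_frame) | set(hyp_by_frame)):
        gts = sorted(gt_by_frame.get(frame, []), key=lambda p: p[0])
        hyps = sorted(hyp_by_frame.get(frame, []), key=lambda p: p[0])
        n_gt += len(gts)

        matched_g, matched_h = set(), set()
        hyp_pos = {hid: j for j, (hid, _) in enumerate(hyps)}
        for i, (gid, gbox) in enumerate(gts):
            prev = last.get(gid)
            if prev is None or prev not in hyp_pos:
                continue
            j = hyp_pos[prev]
            if j not in matched_h and iou_fn(gbox, hyps[j][1]) >= iou_match:
                matched_g.add(i)
                matched_h.add(j)

        free_g = [i for i in range(len(gts)) if i not in matched_g]
        free_h = [j for j in range(len(hyps)) if j not in matched_h]

        best = None  # (-n_matches, cost, pairs)
        k = min(len(free_g), len(free_h))
        for r in range(k, -1, -1):
            # try every way of picking r gts and r hyps, in every order
            from itertools import combinations

            for g_sub in combinations(free_g, r):
                for h_perm in permutations(free_h, r):
                    pairs, cost, ok = [], 0.0, True
                    for i, j in zip(g_sub, h_perm):
                        iou = iou_fn(gts[i][1], hyps[j][1])
                        if iou < iou_match:
                            ok = False
                            break
                        pairs.append((i, j))
                        cost += 1.0 - iou
                    if ok:
                        cand = (-len(pairs), cost, pairs)
                        if best is None or cand[:2] < best[:2]:
                            best = cand
            if best is not None and -best[0] == r:
                break  # no larger matching exists at bigger r (we went downward)

        pairs = best[2] if best else []
        for i, j in pairs:
            gid = gts[i][0]
            hid = hyps[j][0]
            if last.get(gid) is not None and last[gid] != hid:
                n_idsw += 1
            last[gid] = hid
            matched_g.add(i)
            matched_h.add(j)

        n_fn += len(gts) - len(matched_g)
        n_fp += len(hyps) - len(matched_h)

    return n_gt, n_fn, n_fp, n_idsw
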