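"""Self-contained toy sequence tools, invoked as subprocess entry points.

This file is executed by path (``python .../toytools.py <cmd> ...``) from the
toy stage pack, standing in for real aligners/callers so whole pipelines run
and are checkable with no external tools.  It deliberately imports nothing
outside the standard library and never imports the parent package, keeping
process startup cheap for test suites that spawn it hundreds of times.

Text dialects
-------------
* FASTA — standard ``>`` records.
* Toy alignment — line-oriented BAM stand-in: a ``#TOYALN<TAB>1`` header,
  then one tab-separated record per line: read id, contig, 1-based position,
  integer flags (bit 1 = duplicate), read sequence.
* Toy VCF — ``##`` headers, a ``#CHROM`` line with the 8 mandatory columns,
  then tab-separated records.

Every command validates its input dialect and exits loudly on a mismatch:
that defensive check is what makes "validated pipelines never fail at run
time on formats" an observable property rather than an assumption.
"""

import argparse
import sys

ALN_MAGIC = "#TOYALN\t1"
VCF_HEADER = [
    "##fileformat=VCFv4.2",
    "##source=typedflow-toycall",
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]
DUP_FLAG = 1


def die(message):
    sys.stderr.write("toytools: %s\n" % message)
    sys.exit(1)


# ---------------------------------------------------------------------------
# Dialect I/O (defensively validated)
# ---------------------------------------------------------------------------


def read_fasta(path):
    """Parse FASTA into [(id, description, sequence)]; loud on mismatch."""
    records = []
    header = None
    desc = ""
    seq = []
    try:
        lines = open(path).read().splitlines()
    except OSError as exc:
        die("cannot read %s: %s" % (path, exc))
    if lines and not lines[0].startswith(">"):
        die("%s: not FASTA (first line does not start with '>')" % path)
    for line in lines:
        if line.startswith(">"):
            if header is not None:
                records.append((header, desc, "".join(seq)))
            fields = line[1:].split(None, 1)
            if not fields:
                die("%s: empty FASTA header" % path)
            header = fields[0]
            desc = fields[1] if len(fields) > 1 else ""
            seq = []
        else:
            chunk = line.strip()
            if chunk and set(chunk) - set("ACGTNacgtn"):
                die("%s: non-nucleotide characters in sequence: %r" % (path, chunk[:20]))
            seq.append(chunk.upper())
    if header is not None:
        records.append((header, desc, "".join(seq)))
    return records


def write_fasta(path, records, width=60):
    with open(path, "w") as fh:
        for rid, desc, seq in records:
            fh.write(">%s%s\n" % (rid, (" " + desc) if desc else ""))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")


def read_aln(path):
    """Parse the toy alignment dialect into [[read, contig, pos, flags, seq]]."""
    try:
        lines = open(path).read().splitlines()
    except OSError as exc:
        die("cannot read %s: %s" % (path, exc))
    if not lines or lines[0] != ALN_MAGIC:
        die("%s: not a toy alignment file (missing %r header)" % (path, ALN_MAGIC))
    records = []
    for n, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            die("%s:%d: expected 5 tab-separated columns" % (path, n))
        rid, contig, pos, flags, seq = cols
        try:
            pos = int(pos)
            flags = int(flags)
        except ValueError:
            die("%s:%d: position/flags must be integers" % (path, n))
        if pos < 1:
            die("%s:%d: positions are 1-based" % (path, n))
        records.append([rid, contig, pos, flags, seq])
    return records


def write_aln(path, records):
    with open(path, "w") as fh:
        fh.write(ALN_MAGIC + "\n")
        for rid, contig, pos, flags, seq in records:
            fh.write("%s\t%s\t%d\t%d\t%s\n" % (rid, contig, pos, flags, seq))


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------


def cmd_align(args):
    """Place each read on the reference at its minimum-mismatch position.

    Exact matches are found by substring search; reads carrying variants are
    placed via seed hits (read prefix/suffix) scored by Hamming distance.
    Reads exceeding the mismatch cap are dropped.  Deterministic: ties break
    to the leftmost position of the first contig in reference order.
    """
    ref = read_fasta(args.ref)
    reads = []
    for fa in args.reads:
        reads.extend(read_fasta(fa))
    contigs = [(rid, seq) for rid, _, seq in ref]
    records = []
    for rid, _, seq in reads:
        placement = _place(seq, contigs)
        if placement is not None:
            contig, pos0 = placement
            records.append([rid, contig, pos0 + 1, 0, seq])
    write_aln(args.out, records)


def _seed_hits(seq, contig_seq, k=12):
    # non-overlapping k-mer seeds along the read (plus the suffix): a read
    # with m mismatches breaks at most m seeds, so any read within the
    # mismatch cap still yields its true placement as a candidate
    hits = set()
    shifts = list(range(0, max(len(seq) - k + 1, 1), k))
    if len(seq) > k and (len(seq) - k) not in shifts:
        shifts.append(len(seq) - k)
    for shift in shifts:
        seed = seq[shift : shift + k]
        start = contig_seq.find(seed)
        while start != -1:
            off = start - shift
            if 0 <= off <= len(contig_seq) - len(seq):
                hits.add(off)
            start = contig_seq.find(seed, start + 1)
    return hits


def _place(seq, contigs, max_mismatch_frac=0.25):
    cap = max(2, int(len(seq) * max_mismatch_frac))
    best = None  # (mismatches, contig_index, offset)
    for ci, (cid, cseq) in enumerate(contigs):
        exact = cseq.find(seq)
        candidates = _seed_hits(seq, cseq)
        if exact != -1:
            candidates.add(exact)
        for off in sorted(candidates):
            window = cseq[off : off + len(seq)]
            mism = sum(1 for a, b in zip(seq, window) if a != b)
            key = (mism, ci, off)
            if mism <= cap and (best is None or key < best):
                best = key
    if best is None:
        return None
    mism, ci, off = best
    return contigs[ci][0], off


def cmd_fixmates(args):
    """Normalize flags (pass-through transform; validates the dialect)."""
    records = read_aln(args.input)
    for rec in records:
        rec[3] = rec[3] & DUP_FLAG
    write_aln(args.out, records)


def cmd_sort(args):
    """Sort records by (contig, position, read id)."""
    records = read_aln(args.input)
    records.sort(key=lambda r: (r[1], r[2], r[0]))
    write_aln(args.out, records)


def _flag_duplicates(records):
    first_at = {}
    for rec in records:
        key = (rec[1], rec[2])
        keeper = first_at.get(key)
        if keeper is None or rec[0] < keeper[0]:
            first_at[key] = rec
    for rec in records:
        rec[3] = rec[3] | DUP_FLAG if first_at[(rec[1], rec[2])] is not rec else rec[3] & ~DUP_FLAG
    return records


def cmd_markdups(args):
    """Flag all but the first read at each (contig, position) as duplicates."""
    write_aln(args.out, _flag_duplicates(read_aln(args.input)))


def cmd_dedup(args):
    """Remove all but the first read at each (contig, position)."""
    records = _flag_duplicates(read_aln(args.input))
    write_aln(args.out, [r for r in records if not r[3] & DUP_FLAG])


def cmd_call(args):
    """Emit positions where >= min-support reads agree on a non-reference base."""
    ref = {rid: seq for rid, _, seq in read_fasta(args.ref)}
    records = read_aln(args.input)
    support = {}  # (contig, pos1, alt) -> count
    depth = {}  # (contig, pos1) -> count
    for rid, contig, pos, flags, seq in records:
        if contig not in ref:
            die("alignment names unknown contig %r" % contig)
        for i, base in enumerate(seq):
            pos1 = pos + i
            if pos1 > len(ref[contig]):
                break
            depth[(contig, pos1)] = depth.get((contig, pos1), 0) + 1
            refbase = ref[contig][pos1 - 1]
            if base != refbase and base != "N":
                key = (contig, pos1, base)
                support[key] = support.get(key, 0) + 1
    contig_order = {rid: i for i, (rid, seq) in enumerate(ref.items())}
    sites = {}
    for (contig, pos1, alt), count in support.items():
        if count >= args.min_support:
            sites.setdefault((contig, pos1), []).append(alt)
    with open(args.out, "w") as fh:
        fh.write("\n".join(VCF_HEADER) + "\n")
        for contig, pos1 in sorted(sites, key=lambda s: (contig_order[s[0]], s[1])):
            alts = ",".join(sorted(sites[(contig, pos1)]))
            refbase = ref[contig][pos1 - 1]
            fh.write(
                "%s\t%d\t.\t%s\t%s\t.\tPASS\tDP=%d\n"
                % (contig, pos1, refbase, alts, depth[(contig, pos1)])
            )


def cmd_chunk(args):
    """Round-robin shard a FASTA into n files (record i -> shard i mod n)."""
    records = read_fasta(args.input)
    n = len(args.out)
    shards = [[] for _ in range(n)]
    for i, rec in enumerate(records):
        shards[i % n].append(rec)
    for path, shard in zip(args.out, shards):
        write_fasta(path, shard)


def _kmers(seq, k):
    return set(seq[i : i + k] for i in range(len(seq) - k + 1))


def cmd_blast(args):
    """Score each query against each subject by shared k-mer count."""
    queries = read_fasta(args.input)
    subjects = read_fasta(args.subject)
    with open(args.out, "w") as fh:
        fh.write("#TOYHITS\t1\n")
        for qid, _, qseq in queries:
            qk = _kmers(qseq, args.k)
            for sid, _, sseq in subjects:
                score = len(qk & _kmers(sseq, args.k))
                if score > 0:
                    fh.write("%s\t%s\t%d\n" % (qid, sid, score))


def read_hits(path):
    try:
        lines = open(path).read().splitlines()
    except OSError as exc:
        die("cannot read %s: %s" % (path, exc))
    if not lines or lines[0] != "#TOYHITS\t1":
        die("%s: not a toy hits file" % path)
    hits = []
    for n, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            die("%s:%d: expected 3 columns" % (path, n))
        hits.append((cols[0], cols[1], int(cols[2])))
    return hits


def cmd_extract(args):
    """Write each query's top-m subject sequences (score desc, id asc)."""
    hits = read_hits(args.input)
    subjects = {rid: seq for rid, _, seq in read_fasta(args.subject)}
    by_query = {}
    for qid, sid, score in hits:
        by_query.setdefault(qid, []).append((sid, score))
    records = []
    for qid in sorted(by_query):
        ranked = sorted(by_query[qid], key=lambda h: (-h[1], h[0]))[: args.top]
        for sid, score in ranked:
            if sid not in subjects:
                die("hit references unknown subject %r" % sid)
            records.append(("%s|%s|%d" % (qid, sid, score), "", subjects[sid]))
    write_fasta(args.out, records)


def cmd_assemble(args):
    """Rebuild contigs from reads whose headers carry origin=<contig>:<pos>."""
    reads = []
    for fa in args.reads:
        reads.extend(read_fasta(fa))
    placed = {}
    for rid, desc, seq in reads:
        origin = None
        for field in desc.split():
            if field.startswith("origin="):
                origin = field[len("origin=") :]
        if origin is None or ":" not in origin:
            die("read %r lacks an origin=<contig>:<pos> annotation" % rid)
        contig, pos = origin.rsplit(":", 1)
        placed.setdefault(contig, []).append((int(pos), seq))
    records = []
    for contig in sorted(placed):
        length = max(pos - 1 + len(seq) for pos, seq in placed[contig])
        votes = [{} for _ in range(length)]
        for pos, seq in placed[contig]:
            for i, base in enumerate(seq):
                col = votes[pos - 1 + i]
                col[base] = col.get(base, 0) + 1
        consensus = "".join(
            max(sorted(col), key=lambda b: col[b]) if col else "N" for col in votes
        )
        records.append((contig, "assembled", consensus))
    write_fasta(args.out, records)


def cmd_process_contig(args):
    """Per-contig processing: annotate each record with its GC content."""
    records = read_fasta(args.input)
    out = []
    for rid, desc, seq in records:
        gc = 100.0 * sum(1 for b in seq if b in "GC") / len(seq) if seq else 0.0
        out.append((rid, "gc=%.1f" % gc, seq))
    write_fasta(args.out, out)


def cmd_concat(args):
    """Concatenate FASTA records in input order; --sort orders by header."""
    records = []
    for fa in args.inputs:
        records.extend(read_fasta(fa))
    if args.sort:
        records.sort(key=lambda r: (r[0], r[1]))
    write_fasta(args.out, records)


# ---------------------------------------------------------------------------
# CLI plumbing
# ---------------------------------------------------------------------------


def main(argv=None):
    parser = argparse.ArgumentParser(prog="toytools")
    sub = parser.add_subparsers(dest="command", required=True)

    p = sub.add_parser("align")
    p.add_argument("reads", nargs="+")
    p.add_argument("--ref", required=True)
    p.add_argument("-o", dest="out", required=True)
    p.add_argument("-t", dest="threads", type=int, default=1)
    p.set_defaults(func=cmd_align)

    for name, func in (
        ("fixmates", cmd_fixmates),
        ("markdups", cmd_markdups),
        ("dedup", cmd_dedup),
        ("process-contig", cmd_process_contig),
    ):
        p = sub.add_parser(name)
        p.add_argument("input")
        p.add_argument("-o", dest="out", required=True)
        p.set_defaults(func=func)

    p = sub.add_parser("sort")
    p.add_argument("input")
    p.add_argument("-@", dest="threads", type=int, default=1)
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_sort)

    p = sub.add_parser("call")
    p.add_argument("input")
    p.add_argument("--ref", required=True)
    p.add_argument("--min-support", type=int, default=2)
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_call)

    p = sub.add_parser("chunk")
    p.add_argument("input")
    p.add_argument("-o", dest="out", nargs="+", required=True)
    p.set_defaults(func=cmd_chunk)

    p = sub.add_parser("blast")
    p.add_argument("input")
    p.add_argument("--subject", required=True)
    p.add_argument("-k", type=int, default=8)
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_blast)

    p = sub.add_parser("extract")
    p.add_argument("input")
    p.add_argument("--subject", required=True)
    p.add_argument("-m", dest="top", type=int, default=3)
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_extract)

    p = sub.add_parser("assemble")
    p.add_argument("reads", nargs="+")
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_assemble)

    p = sub.add_parser("concat")
    p.add_argument("inputs", nargs="+")
    p.add_argument("--sort", action="store_true")
    p.add_argument("-o", dest="out", required=True)
    p.set_defaults(func=cmd_concat)

    args = parser.parse_args(argv)
    args.func(args)
    return 0


if __name__ == "__main__":
    sys.exit(main())
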