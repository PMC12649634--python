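"""Bundled word lists: stop words for header generation, verb cues for the
rule-based proposition extractor."""

from __future__ import annotations

#: Compact English stop-word list used when scoring header phrases.
STOPWORDS = frozenset(
    """a about above after again all an and any are as at be because been
    before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my no nor
    not of off on once only or other our out over own same she should so
    some such than that the their them then there these they this those
    through to too under until unless up very was we were what when where
    which while who whom why will with you your""".split()
)

#: Finite-verb cues for the proposition splitter.  Clause-conjunction splits
#: only fire when both sides carry one of these (or a -s/-ed/-ing form).
VERB_CUES = frozenset(
    """is are was were be been being am has have had do does did can could
    may might must shall should will would keep keeps avoid avoids remove
    removes begin begins start starts stop stops apply applies take takes
    use uses call calls contact contacts expect expects return returns
    sleep sleeps elevate elevates wear wears stay stays irrigate irrigates
    clean cleans change changes resume resumes continue continues report
    reports seek seeks notify notifies schedule schedules follow follows
    monitor monitors check checks drink drinks eat eats rest rests""".split()
)
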