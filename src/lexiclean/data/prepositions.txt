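# Closed-class prepositions/conjunctions blocking syntactic inversion.
of
in
on
for
to
by
with
at
from
and
or
nor
but
as
versus
vs
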