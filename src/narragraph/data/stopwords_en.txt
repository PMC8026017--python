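# English stop-words (function words / liaison terms)
a
an
and
are
as
at
be
been
but
by
did
do
does
for
from
had
has
have
he
her
hers
him
his
i
if
in
into
is
it
its
me
my
no
nor
not
of
off
on
or
our
she
so
that
the
their
them
then
there
these
they
this
those
to
up
was
we
were
what
when
where
which
who
will
with
you
your
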