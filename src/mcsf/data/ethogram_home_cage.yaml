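# Home cage change test ethogram: social behaviors grouped by functional
# category, plus burrowing as a standalone (non-social, defensive)
# behavior reported in raw seconds and bouts.  Session duration 600 s.
test_type: home_cage_change
session_duration: 600.0
categories:
  neutral:
    head_head: The head of the rat touches the head of the other rat
    nose_side: The rat sniffs between the ventral region and the back of the other rat
    nose_nose: The rat sniffs the other rat's nose in an equal sniff
    passing: The rat passes the other rat in a direct meeting or from behind
  dominant:
    head_tail: The head of the rat touches the tail of the other rat
    nose_genitals: The nose of the rat touches the genitals of the other rat
    following: The rat follows the other rat for more than two steps
    approaching: Direct walking/running approach toward the other rat
    nuzzling: The rat sniffs/bites/grooms the other rat between nose tip and ventral region
    mount1: The rat rears and leans its front legs on the other rat's back from behind
  aggressive:
    mount2: Mounting with copulation movements
    chasing: The rat runs after the other rat for more than two steps
    fight: Rapid rolling, jumping and biting of both animals in close contact
  submissive:
    avoiding: The rat moves or faces away when the other rat approaches
    crawling_under: The rat crawls under the other rat
    submissive_posture: Lying on the back with the other rat standing/leaning over
standalone:
  burrowing: Shuffling of bedding in front of and beside the rat (defensive)
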