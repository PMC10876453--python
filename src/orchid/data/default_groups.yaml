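# Default ORCHID scoring configuration.
#
# Structure (which groups are recall- vs FPQ-sourced, which ratings are
# positive vs threshold, the sign conventions) is canonical; the numeric
# weights, thresholds and standard portions are a documented approximation
# in the spirit of ENNS/GEMRCN serving conventions and are meant to be
# edited.  Cooked ham's 50 g portion is the one documented reference value.
groups:
  meat_excluding_poultry:
    label: "Meat excluding poultry"
    portion_g: 100
    source: recall
    rating: threshold
    weight: -1
    threshold: 3
  cooked_ham:
    label: "Cooked ham"
    portion_g: 50
    source: recall
    rating: positive
    weight: 1
  deli_meats_excluding_cooked_ham:
    label: "Deli meats excluding cooked ham"
    portion_g: 50
    source: recall
    rating: threshold
    weight: -2
    threshold: 1
  milk_and_fresh_dairy_products:
    label: "Milk and fresh dairy products"
    portion_g: 125
    source: recall
    rating: positive
    weight: 1
  cheese:
    label: "Cheese"
    portion_g: 30
    source: recall
    rating: positive
    weight: 1
  refined_starches_and_potatoes:
    label: "Refined starches and potatoes"
    portion_g: 150
    source: recall
    rating: positive
    weight: 1
  vegetables:
    label: "Vegetables"
    portion_g: 200
    source: recall
    rating: positive
    weight: 2
  fruits:
    label: "Fruits"
    portion_g: 150
    source: recall
    rating: positive
    weight: 2
  oils:
    label: "Oils"
    portion_g: 10
    source: recall
    rating: positive
    weight: 1
  butter_margarine_and_fresh_cream:
    label: "Butter, margarine and fresh cream"
    portion_g: 10
    source: recall
    rating: threshold
    weight: -1
    threshold: 3
  salted_aperitif_products:
    label: "Salted aperitif products"
    portion_g: 30
    source: recall
    rating: threshold
    weight: -2
    threshold: 1
  sweetened_products:
    label: "Sweetened products"
    portion_g: 30
    source: recall
    rating: threshold
    weight: -2
    threshold: 3
  sweetened_beverages:
    label: "Sweetened beverages"
    portion_g: 150
    source: recall
    rating: threshold
    weight: -2
    threshold: 0
  poultry:
    label: "Poultry"
    portion_g: 100
    source: fpq
    rating: positive
    weight: 2
  eggs:
    label: "Eggs"
    portion_g: 50
    source: fpq
    rating: positive
    weight: 2
  fatty_fish:
    label: "Fatty fish"
    portion_g: 100
    source: fpq
    rating: positive
    weight: 3
  lean_fish_and_shellfish:
    label: "Lean fish and shellfish"
    portion_g: 100
    source: fpq
    rating: positive
    weight: 3
  legumes:
    label: "Legumes"
    portion_g: 150
    source: fpq
    rating: positive
    weight: 3
  nuts:
    label: "Nuts"
    portion_g: 30
    source: fpq
    rating: positive
    weight: 2
  wholemeal_or_semi_wholemeal_products:
    label: "Wholemeal or semi-wholemeal products"
    portion_g: 100
    source: fpq
    rating: positive
    weight: 2
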