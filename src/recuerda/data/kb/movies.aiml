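<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="movies" description="películas favoritas del paciente">
    <category role="trigger">
      <pattern>PELÍCULA</pattern>
      <template><random>
        <li>¡El cine es mágico! ¿Es verdad que tu película favorita es <get name="pelicula_favorita"/>?</li>
        <li>¿Qué película te gusta ver una y otra vez?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ PELÍCULA</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>PELÍCULA _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PELÍCULA _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>PELÍCULAS</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PELÍCULAS</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>PELÍCULAS _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PELÍCULAS _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CINE</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CINE</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CINE _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CINE _</pattern>
      <template><srai>PELÍCULA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Gran elección! ¿Qué parte de <get name="pelicula_favorita"/> te gusta más?</li>
        <li>¿Con quién viste <get name="pelicula_favorita"/> por primera vez?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Gracias por decirme. ¿Cuál es tu película favorita entonces?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Las películas dan mucho de qué hablar. ¿Cuál recuerdas con cariño?</li>
        <li>Ir al cine era toda una aventura. ¿Me cuentas de alguna vez que fuiste?</li>
      </random></template>
    </category>
  </topic>
</aiml>
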